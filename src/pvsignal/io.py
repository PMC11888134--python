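"""Readers and writers for the relational ICSR tables and vocabulary files.

A report database is stored as three delimited files keyed by ``report_id``:

``reports.csv``
    report_id, age_group (or a raw ``age_years`` column binned at load),
    sex, serious, seriousness_criteria (``;``-joined tokens)
``drugs.csv``
    report_id, drug_code, role, daily_dose_mg, start_date, stop_date,
    dechallenge, rechallenge
``reactions.csv``
    report_id, term, onset_date

Dates are ISO-8601. Unrecognized enum values map to ``unknown`` rather than
failing the load; structural problems (missing columns, duplicate or dangling
report ids) raise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import (
    AGE_LEVELS,
    DECHALLENGE_LEVELS,
    DRUG_ROLES,
    RECHALLENGE_LEVELS,
    SERIOUS_LEVELS,
    SERIOUSNESS_CRITERIA,
    SEX_LEVELS,
    DrugEntry,
    ICSRReport,
    ReactionEntry,
    Vocabulary,
    bin_age,
)

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A table lacks a required column or uses an unknown output schema."""


class IntegrityError(ValueError):
    """Referential or uniqueness violation across the three ICSR tables."""


class VocabularyError(ValueError):
    """Vocabulary file invalid (e.g. empty SMQ term section)."""


REPORT_COLUMNS = ["report_id", "age_group", "sex", "serious", "seriousness_criteria"]
DRUG_COLUMNS = [
    "report_id",
    "drug_code",
    "role",
    "daily_dose_mg",
    "start_date",
    "stop_date",
    "dechallenge",
    "rechallenge",
]
REACTION_COLUMNS = ["report_id", "term", "onset_date"]


@dataclass
class ICSRFrames:
    """Tabular view of a report database (the fast path for large inputs)."""

    reports: pd.DataFrame
    drugs: pd.DataFrame
    reactions: pd.DataFrame

    @property
    def n_reports(self) -> int:
        return len(self.reports)


def _require_columns(df: pd.DataFrame, required: Sequence[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table missing required column(s): {', '.join(missing)}")


def _map_enum(series: pd.Series, levels: Sequence[str]) -> pd.Series:
    s = series.fillna("").astype(str).str.strip().str.lower()
    return s.where(s.isin(levels), "unknown").replace({"": "unknown"})


def read_frames(
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> ICSRFrames:
    """Read and validate the three-table database into dataframes.

    Raises :class:`SchemaError` on missing columns and :class:`IntegrityError`
    on duplicate report ids or drug/reaction rows whose ``report_id`` does
    not exist in the reports table.
    """
    reports = pd.read_csv(reports_path, dtype=str)
    drugs = pd.read_csv(drugs_path, dtype=str)
    reactions = pd.read_csv(reactions_path, dtype=str)

    if "age_group" not in reports.columns and "age_years" in reports.columns:
        age_years = pd.to_numeric(reports["age_years"], errors="coerce")
        reports["age_group"] = [bin_age(v) for v in age_years]
    _require_columns(reports, REPORT_COLUMNS, "reports")
    _require_columns(drugs, DRUG_COLUMNS, "drugs")
    _require_columns(reactions, REACTION_COLUMNS, "reactions")

    dup = reports["report_id"].duplicated()
    if dup.any():
        example = reports.loc[dup, "report_id"].iloc[0]
        raise IntegrityError(f"duplicate report_id in reports table: {example!r}")

    known = set(reports["report_id"])
    for name, df in (("drugs", drugs), ("reactions", reactions)):
        dangling = ~df["report_id"].isin(known)
        if dangling.any():
            example = df.loc[dangling, "report_id"].iloc[0]
            raise IntegrityError(
                f"{name} row references absent report_id {example!r}"
            )

    reports = reports.copy()
    reports["age_group"] = _map_enum(reports["age_group"], AGE_LEVELS)
    reports["sex"] = _map_enum(reports["sex"], SEX_LEVELS)
    reports["serious"] = _map_enum(reports["serious"], SERIOUS_LEVELS)
    reports["seriousness_criteria"] = reports["seriousness_criteria"].fillna("")

    drugs = drugs.copy()
    drugs["drug_code"] = drugs["drug_code"].fillna("").str.strip().str.upper()
    drugs["role"] = _map_enum(drugs["role"], DRUG_ROLES)
    # unrecognized role defaults to the most conservative reading
    drugs.loc[~drugs["role"].isin(DRUG_ROLES), "role"] = "concomitant"
    drugs["role"] = drugs["role"].replace({"unknown": "concomitant"})
    drugs["daily_dose_mg"] = pd.to_numeric(drugs["daily_dose_mg"], errors="coerce")
    neg = drugs["daily_dose_mg"] < 0
    if neg.any():
        raise IntegrityError("negative daily_dose_mg in drugs table")
    for col in ("start_date", "stop_date"):
        drugs[col] = pd.to_datetime(drugs[col], errors="coerce")
    drugs["dechallenge"] = _map_enum(drugs["dechallenge"], DECHALLENGE_LEVELS)
    drugs["rechallenge"] = _map_enum(drugs["rechallenge"], RECHALLENGE_LEVELS)

    reactions = reactions.copy()
    reactions["term"] = reactions["term"].fillna("").str.strip()
    reactions = reactions[reactions["term"] != ""]
    reactions["onset_date"] = pd.to_datetime(reactions["onset_date"], errors="coerce")

    return ICSRFrames(reports=reports, drugs=drugs, reactions=reactions)


def frames_to_reports(frames: ICSRFrames) -> list[ICSRReport]:
    """Materialize dataframes as a list of :class:`ICSRReport` objects."""
    drugs_by_id: dict[str, list[DrugEntry]] = {}
    for row in frames.drugs.itertuples(index=False):
        entry = DrugEntry(
            report_id=row.report_id,
            drug_code=row.drug_code,
            role=row.role,
            daily_dose_mg=None if pd.isna(row.daily_dose_mg) else float(row.daily_dose_mg),
            start_date=None if pd.isna(row.start_date) else row.start_date.date(),
            stop_date=None if pd.isna(row.stop_date) else row.stop_date.date(),
            dechallenge=row.dechallenge,
            rechallenge=row.rechallenge,
        )
        drugs_by_id.setdefault(row.report_id, []).append(entry)
    reactions_by_id: dict[str, list[ReactionEntry]] = {}
    for row in frames.reactions.itertuples(index=False):
        entry = ReactionEntry(
            report_id=row.report_id,
            term=row.term,
            onset_date=None if pd.isna(row.onset_date) else row.onset_date.date(),
        )
        reactions_by_id.setdefault(row.report_id, []).append(entry)

    reports: list[ICSRReport] = []
    for row in frames.reports.itertuples(index=False):
        tokens = [t for t in str(row.seriousness_criteria).split(";") if t.strip()]
        criteria = frozenset(
            t.strip().lower() for t in tokens if t.strip().lower() in SERIOUSNESS_CRITERIA
        )
        if row.serious != "yes":
            criteria = frozenset()
        reports.append(
            ICSRReport(
                report_id=row.report_id,
                age_group=row.age_group,
                sex=row.sex,
                serious=row.serious,
                seriousness_criteria=criteria,
                drugs=drugs_by_id.get(row.report_id, []),
                reactions=reactions_by_id.get(row.report_id, []),
            )
        )
    return reports


def reports_to_frames(reports: Iterable[ICSRReport]) -> ICSRFrames:
    """Tabular view of a list of reports (inverse of :func:`frames_to_reports`)."""
    rep_rows, drug_rows, rx_rows = [], [], []
    for r in reports:
        rep_rows.append(
            {
                "report_id": r.report_id,
                "age_group": r.age_group,
                "sex": r.sex,
                "serious": r.serious,
                "seriousness_criteria": ";".join(sorted(r.seriousness_criteria)),
            }
        )
        for d in r.drugs:
            drug_rows.append(
                {
                    "report_id": d.report_id,
                    "drug_code": d.drug_code,
                    "role": d.role,
                    "daily_dose_mg": np.nan if d.daily_dose_mg is None else d.daily_dose_mg,
                    "start_date": pd.NaT if d.start_date is None else pd.Timestamp(d.start_date),
                    "stop_date": pd.NaT if d.stop_date is None else pd.Timestamp(d.stop_date),
                    "dechallenge": d.dechallenge,
                    "rechallenge": d.rechallenge,
                }
            )
        for x in r.reactions:
            rx_rows.append(
                {
                    "report_id": x.report_id,
                    "term": x.term,
                    "onset_date": pd.NaT if x.onset_date is None else pd.Timestamp(x.onset_date),
                }
            )
    reports_df = pd.DataFrame(rep_rows, columns=REPORT_COLUMNS)
    drugs_df = pd.DataFrame(drug_rows, columns=DRUG_COLUMNS)
    reactions_df = pd.DataFrame(rx_rows, columns=REACTION_COLUMNS)
    if len(drugs_df):
        drugs_df["start_date"] = pd.to_datetime(drugs_df["start_date"])
        drugs_df["stop_date"] = pd.to_datetime(drugs_df["stop_date"])
    if len(reactions_df):
        reactions_df["onset_date"] = pd.to_datetime(reactions_df["onset_date"])
    return ICSRFrames(reports=reports_df, drugs=drugs_df, reactions=reactions_df)


def read_database(
    reports_path: str | Path,
    drugs_path: str | Path,
    reactions_path: str | Path,
) -> list[ICSRReport]:
    """Read a three-table database as fully joined :class:`ICSRReport` objects."""
    return frames_to_reports(read_frames(reports_path, drugs_path, reactions_path))


def write_frames(frames: ICSRFrames, out_dir: str | Path) -> dict[str, Path]:
    """Write the three tables to ``out_dir`` (reports/drugs/reactions .csv)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reports": out / "reports.csv",
        "drugs": out / "drugs.csv",
        "reactions": out / "reactions.csv",
    }
    frames.reports.to_csv(paths["reports"], index=False)
    drugs = frames.drugs.copy()
    for col in ("start_date", "stop_date"):
        drugs[col] = pd.to_datetime(drugs[col]).dt.strftime("%Y-%m-%d")
    drugs.to_csv(paths["drugs"], index=False)
    reactions = frames.reactions.copy()
    reactions["onset_date"] = pd.to_datetime(reactions["onset_date"]).dt.strftime("%Y-%m-%d")
    reactions.to_csv(paths["reactions"], index=False)
    return paths


def write_database(reports: Iterable[ICSRReport], out_dir: str | Path) -> dict[str, Path]:
    """Write a list of reports to the three-table CSV layout."""
    return write_frames(reports_to_frames(reports), out_dir)


# Vocabulary ----------------------------------------------------------------

_VOCAB_OPTIONAL_SECTIONS = (
    "antihypertensive_codes",
    "hypertensive_inducer_codes",
    "comparator_population_codes",
    "stroke_terms",
    "mi_terms",
)


def load_vocabulary(path: str | Path) -> Vocabulary:
    """Load a vocabulary YAML file.

    Required: non-empty ``smq_terms`` and ``target_drugs``.  Optional code
    and term sections default to empty with a logged warning, which disables
    the analyses that depend on them.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, Mapping):
        raise VocabularyError("vocabulary file must be a mapping of sections")
    smq = raw.get("smq_terms") or []
    if not smq:
        raise VocabularyError("vocabulary smq_terms section is empty")
    target = raw.get("target_drugs") or {}
    if not target:
        raise VocabularyError("vocabulary target_drugs section is empty")
    kwargs: dict[str, frozenset[str]] = {}
    for section in _VOCAB_OPTIONAL_SECTIONS:
        values = raw.get(section)
        if not values:
            logger.warning("vocabulary section %r missing or empty; analyses using it are disabled", section)
            values = []
        kwargs[section] = frozenset(values)
    return Vocabulary(
        smq_terms=frozenset(smq),
        target_drugs={label: frozenset(codes) for label, codes in target.items()},
        **kwargs,
    )


def default_vocabulary_path() -> Path:
    """Path of the vocabulary fixture shipped with the package (synthetic analog)."""
    return Path(__file__).parent / "data" / "default_vocabulary.yaml"


def load_default_vocabulary() -> Vocabulary:
    return load_vocabulary(default_vocabulary_path())


# Output tables -------------------------------------------------------------

#: Output schemas: column order, columns rendered to 2 decimals (ratios) and
#: to 1 decimal (percentages / day counts) in the human-readable file.  The
#: machine-readable companion ``<name>_raw.csv`` keeps full precision.
TABLE_SCHEMAS: dict[str, dict[str, list[str]]] = {
    "signal_table": {
        "columns": [
            "drug", "cases", "non_cases",
            "ror", "ci_low", "ci_high",
            "aror", "aci_low", "aci_high", "signal",
        ],
        "round2": ["ror", "ci_low", "ci_high", "aror", "aci_low", "aci_high"],
        "round1": [],
    },
    "dose_table": {
        "columns": [
            "drug", "median_dose_mg",
            "low_cases", "low_non_cases", "low_ror", "low_ci_low", "low_ci_high",
            "low_aror", "low_aci_low", "low_aci_high",
            "high_cases", "high_non_cases", "high_ror", "high_ci_low", "high_ci_high",
            "high_aror", "high_aci_low", "high_aci_high",
            "trend_p", "evaluated",
        ],
        "round2": [
            "median_dose_mg",
            "low_ror", "low_ci_low", "low_ci_high", "low_aror", "low_aci_low", "low_aci_high",
            "high_ror", "high_ci_low", "high_ci_high", "high_aror", "high_aci_low", "high_aci_high",
            "trend_p",
        ],
        "round1": [],
    },
    "tto_table": {
        "columns": ["drug", "n_available", "median_days", "iqr_low_days", "iqr_high_days"],
        "round2": [],
        "round1": ["median_days", "iqr_low_days", "iqr_high_days"],
    },
    "challenge_table": {
        "columns": ["drug", "n_positive_dechallenge", "n_positive_rechallenge"],
        "round2": [],
        "round1": [],
    },
    "cohort_summary": {
        "columns": ["field", "count", "denominator", "percent"],
        "round2": [],
        "round1": ["percent"],
    },
}


def _fmt(value, ndigits: int) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    return f"{float(value):.{ndigits}f}"


def write_table(rows: Sequence[Mapping], path: str | Path, schema_name: str) -> Path:
    """Write an output table in a stable column order.

    Ratios are rendered to 2 decimals and percentages/day summaries to
    1 decimal; a ``<stem>_raw.csv`` companion retains full precision.
    Unknown ``schema_name`` raises :class:`SchemaError`.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown output schema {schema_name!r}")
    schema = TABLE_SCHEMAS[schema_name]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(rows), columns=schema["columns"])
    raw_path = path.with_name(path.stem + "_raw" + path.suffix)
    df.to_csv(raw_path, index=False)
    rendered = df.copy().astype(object)
    for col in schema["round2"]:
        rendered[col] = [_fmt(v, 2) for v in df[col]]
    for col in schema["round1"]:
        rendered[col] = [_fmt(v, 1) for v in df[col]]
    rendered = rendered.where(pd.notna(rendered), "NA")
    rendered.to_csv(path, index=False)
    return path
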