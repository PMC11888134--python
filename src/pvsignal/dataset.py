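"""Case/non-case analytic dataset construction.

Each adult report is classified as a *case* (at least one reaction term in
the event term list) or a *non-case*, and per target drug as exposed or
unexposed by ATC code.  Reports with unknown age are excluded: the design
restricts to the adult demographic, which requires a known adult age.
Unknown sex is retained as its own level so crude and adjusted analyses run
on the identical record set.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import ICSRFrames, reports_to_frames
from .types import ContingencyTable, ICSRReport, Vocabulary, canonical_term, code_matches

logger = logging.getLogger(__name__)

ROLE_POLICIES = ("any_role", "suspect_only")
POPULATION_FILTERS = ("whole_database", "antidepressant_only")

#: Pooled class row label: exposure to at least one target drug.
CLASS_LABEL = "SRI class"


# Report-level classifiers --------------------------------------------------


def classify_case(report: ICSRReport, vocabulary: Vocabulary) -> bool:
    """True when at least one reaction term matches the event term list.

    Classification is at report level: several matching terms still make
    one case.
    """
    return any(vocabulary.is_smq_term(rx.term) for rx in report.reactions)


def classify_exposure(
    report: ICSRReport,
    drug_codes: frozenset[str] | set[str],
    role_policy: str = "any_role",
) -> bool:
    """True when at least one drug entry carries a matching ATC code.

    Under ``any_role`` the drug counts regardless of its reported role
    (suspect, concomitant or interacting); ``suspect_only`` restricts to
    suspect entries (the sensitivity analysis).
    """
    if role_policy not in ROLE_POLICIES:
        raise ValueError(f"invalid role_policy {role_policy!r}")
    for entry in report.drugs:
        if role_policy == "suspect_only" and entry.role != "suspect":
            continue
        if code_matches(entry.drug_code, drug_codes):
            return True
    return False


# Analytic dataset -----------------------------------------------------------


@dataclass
class AnalyticRecord:
    """One report's analysis-ready classification."""

    report_id: str
    is_case: bool
    exposures: dict[str, bool]
    suspect_exposures: dict[str, bool]
    age_group: str
    sex: str
    has_antihypertensive: bool
    has_hypertensive_inducer: bool
    in_comparator_population: bool
    doses: dict[str, Optional[float]] = field(default_factory=dict)


class _CodeMatcher:
    """Prefix-matches ATC codes against code sets via the unique code values
    (drug tables repeat few distinct codes, so this is far cheaper than
    row-wise string operations)."""

    def __init__(self, codes: pd.Series) -> None:
        uniq, inv = np.unique(codes.astype(str).to_numpy(), return_inverse=True)
        self._inv = inv
        self._canon = np.char.upper(np.char.strip(uniq.astype(str)))

    def match(self, code_set: frozenset[str]) -> np.ndarray:
        if not code_set:
            return np.zeros(len(self._inv), dtype=bool)
        mask = np.zeros(len(self._canon), dtype=bool)
        for prefix in code_set:
            mask |= np.char.startswith(self._canon, prefix)
        return mask[self._inv]


@dataclass
class AnalyticDataset:
    """Tabular case/non-case dataset plus the vocabulary that produced it.

    The underlying dataframe has one row per retained report with columns
    ``is_case``, ``age_group``, ``sex``, ``has_antihypertensive``,
    ``has_inducer``, ``in_comparator`` and, per drug label, ``exp_<label>``,
    ``sus_<label>`` and ``dose_<label>``.
    """

    df: pd.DataFrame
    vocabulary: Vocabulary
    role_policy: str = "any_role"
    population_filter: str = "whole_database"

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def drug_labels(self) -> list[str]:
        return self.vocabulary.drug_labels

    def exposure_mask(self, drug: str) -> np.ndarray:
        """Exposure indicator for one drug (or the pooled class) under the
        dataset's role policy."""
        prefix = "sus_" if self.role_policy == "suspect_only" else "exp_"
        if drug == CLASS_LABEL:
            cols = [prefix + d for d in self.drug_labels]
            return self.df[cols].to_numpy().any(axis=1)
        col = prefix + drug
        if col not in self.df.columns:
            raise KeyError(f"unknown drug {drug!r}")
        return self.df[col].to_numpy()

    def case_mask(self) -> np.ndarray:
        return self.df["is_case"].to_numpy()

    def dose_values(self, drug: str) -> np.ndarray:
        return self.df["dose_" + drug].to_numpy()

    def contingency(self, drug: str) -> ContingencyTable:
        return contingency_from_masks(self.case_mask(), self.exposure_mask(drug))

    def records(self) -> list[AnalyticRecord]:
        labels = self.drug_labels
        out = []
        for d in self.df.to_dict(orient="records"):
            out.append(
                AnalyticRecord(
                    report_id=d["report_id"],
                    is_case=bool(d["is_case"]),
                    exposures={lab: bool(d["exp_" + lab]) for lab in labels},
                    suspect_exposures={lab: bool(d["sus_" + lab]) for lab in labels},
                    age_group=d["age_group"],
                    sex=d["sex"],
                    has_antihypertensive=bool(d["has_antihypertensive"]),
                    has_hypertensive_inducer=bool(d["has_inducer"]),
                    in_comparator_population=bool(d["in_comparator"]),
                    doses={
                        lab: None if np.isnan(d["dose_" + lab]) else float(d["dose_" + lab])
                        for lab in labels
                    },
                )
            )
        return out


def contingency_from_masks(case: np.ndarray, exposed: np.ndarray) -> ContingencyTable:
    a = int(np.sum(exposed & case))
    b = int(np.sum(exposed & ~case))
    c = int(np.sum(~exposed & case))
    d = int(np.sum(~exposed & ~case))
    return ContingencyTable(a=a, b=b, c=c, d=d)


def contingency(records_or_dataset, drug: str) -> ContingencyTable:
    """2x2 table for one drug from an :class:`AnalyticDataset` or a list of
    :class:`AnalyticRecord`."""
    if isinstance(records_or_dataset, AnalyticDataset):
        return records_or_dataset.contingency(drug)
    records = list(records_or_dataset)
    case = np.array([r.is_case for r in records], dtype=bool)
    if drug == CLASS_LABEL:
        exposed = np.array([any(r.exposures.values()) for r in records], dtype=bool)
    else:
        exposed = np.array([r.exposures[drug] for r in records], dtype=bool)
    return contingency_from_masks(case, exposed)


def build_analytic_frame(
    frames: ICSRFrames,
    vocabulary: Vocabulary,
    role_policy: str = "any_role",
    population_filter: str = "whole_database",
) -> AnalyticDataset:
    """Vectorized analytic-dataset construction from the tabular database."""
    if role_policy not in ROLE_POLICIES:
        raise ValueError(f"invalid role_policy {role_policy!r}")
    if population_filter not in POPULATION_FILTERS:
        raise ValueError(f"invalid population_filter {population_filter!r}")

    reports = frames.reports
    drugs = frames.drugs
    reactions = frames.reactions

    df = reports[["report_id", "age_group", "sex"]].copy()
    df = df[df["age_group"] != "unknown"]  # adult restriction needs a known age

    # Case status: any canonical reaction term in the event term list.
    terms = reactions["term"].astype(str).map(canonical_term)
    case_ids = set(reactions.loc[terms.isin(vocabulary.smq_terms), "report_id"])
    df["is_case"] = df["report_id"].isin(case_ids)

    matcher = _CodeMatcher(drugs["drug_code"])
    drug_ids = drugs["report_id"].to_numpy()
    suspect = (drugs["role"] == "suspect").to_numpy()

    def _ids(mask: np.ndarray) -> set[str]:
        return set(drug_ids[mask])

    new_cols: dict[str, object] = {}
    for label in vocabulary.drug_labels:
        dmask = matcher.match(vocabulary.target_drugs[label])
        exp = df["report_id"].isin(_ids(dmask))
        new_cols["exp_" + label] = exp
        new_cols["sus_" + label] = df["report_id"].isin(_ids(dmask & suspect))
        dose = (
            drugs.loc[dmask & drugs["daily_dose_mg"].notna().to_numpy(), ["report_id", "daily_dose_mg"]]
            .groupby("report_id")["daily_dose_mg"]
            .max()
        )
        dose_col = df["report_id"].map(dose)
        dose_col[~exp] = np.nan
        new_cols["dose_" + label] = dose_col

    new_cols["has_antihypertensive"] = df["report_id"].isin(
        _ids(matcher.match(vocabulary.antihypertensive_codes))
    )
    new_cols["has_inducer"] = df["report_id"].isin(
        _ids(matcher.match(vocabulary.hypertensive_inducer_codes))
    )
    new_cols["in_comparator"] = df["report_id"].isin(
        _ids(matcher.match(vocabulary.comparator_population_codes))
    )
    df = pd.concat([df, pd.DataFrame(new_cols, index=df.index)], axis=1)

    if population_filter == "antidepressant_only":
        df = df[df["in_comparator"]]
        if df.empty:
            msg = "antidepressant_only filter retained no reports"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)

    df = df.reset_index(drop=True)
    return AnalyticDataset(
        df=df,
        vocabulary=vocabulary,
        role_policy=role_policy,
        population_filter=population_filter,
    )


def build_analytic_dataset(
    reports: Iterable[ICSRReport] | ICSRFrames,
    vocabulary: Vocabulary,
    role_policy: str = "any_role",
    population_filter: str = "whole_database",
) -> AnalyticDataset:
    """Build the analytic dataset from joined reports or tabular frames."""
    frames = reports if isinstance(reports, ICSRFrames) else reports_to_frames(list(reports))
    return build_analytic_frame(frames, vocabulary, role_policy, population_filter)
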