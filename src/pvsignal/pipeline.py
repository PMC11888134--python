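"""Config-driven orchestration of the full analysis set.

``run_analysis`` reproduces the complete study battery from a three-table
database and a vocabulary: the main any-role analysis, the suspect-only and
antidepressant-population sensitivity analyses, the dose-effect tables and
the descriptive tables, each written as a rendered CSV plus a full-precision
companion, together with a YAML run manifest (config hash, input checksums,
row counts).  ``simulate_and_validate`` powers the calibration suite:
replicate synthetic databases are generated and pushed through the same
estimators, and empirical signal rate, CI coverage and estimator bias are
reported against the planted truth.
"""
from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import CLASS_LABEL
from .disproportionality import compute_ror, signal_flag
from .io import load_vocabulary, write_table
from .model import CaseNonCaseStudy
from .simulate import SyntheticConfig, generate_frames
from .types import SignalResult, Vocabulary

logger = logging.getLogger(__name__)

ANALYSES = ("main", "suspect_only", "n06a_population", "dose", "descriptives")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One orchestrated analysis run."""

    reports_path: str
    drugs_path: str
    reactions_path: str
    vocabulary_path: Optional[str] = None
    analyses: tuple[str, ...] = ANALYSES
    out_dir: str = "pvsignal_out"
    n_total_reports: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.analyses) - set(ANALYSES)
        if bad:
            raise ValueError(f"unknown analyses requested: {sorted(bad)}")


def _signal_rows(results: list[SignalResult]) -> list[dict]:
    return [
        {
            "drug": r.drug,
            "cases": r.a,
            "non_cases": r.b,
            "ror": r.ror,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "aror": r.aror,
            "aci_low": r.aci_low,
            "aci_high": r.aci_high,
            "signal": r.signal,
        }
        for r in results
    ]


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_analysis(config: RunConfig) -> dict[str, Path]:
    """Run the requested analyses; write one CSV per output table plus a
    run manifest.  Any stage failure removes partial outputs and raises
    :class:`PipelineError` naming the stage."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    row_counts: dict[str, int] = {}
    n_tests = 0
    stage = "load"
    t0 = time.time()
    try:
        vocab = load_vocabulary(config.vocabulary_path) if config.vocabulary_path else None
        study = CaseNonCaseStudy.from_csv(
            config.reports_path,
            config.drugs_path,
            config.reactions_path,
            vocabulary_path=config.vocabulary_path,
        )
        logger.info("stage %s done in %.2fs (%d analytic records)", stage, time.time() - t0, study.n_records)

        def emit(name: str, rows: list[dict], schema: str) -> None:
            path = out_dir / f"{name}.csv"
            write_table(rows, path, schema)
            written[name] = path
            row_counts[name] = len(rows)

        if "main" in config.analyses:
            stage = "main"
            t = time.time()
            res = study.fit(adjusted=True)
            emit("signal_table", _signal_rows(res.results), "signal_table")
            n_tests += sum(1 for r in res.results if r.ror is not None)
            logger.info("stage main done in %.2fs", time.time() - t)

        if "suspect_only" in config.analyses:
            stage = "suspect_only"
            t = time.time()
            sens = CaseNonCaseStudy(
                study._frames if study._frames is not None else study._reports,
                vocabulary=study.vocabulary,
                role_policy="suspect_only",
            ).fit(adjusted=True)
            emit("signal_table_suspect_only", _signal_rows(sens.results), "signal_table")
            n_tests += sum(1 for r in sens.results if r.ror is not None)
            logger.info("stage suspect_only done in %.2fs", time.time() - t)

        if "n06a_population" in config.analyses:
            stage = "n06a_population"
            t = time.time()
            sens = CaseNonCaseStudy(
                study._frames if study._frames is not None else study._reports,
                vocabulary=study.vocabulary,
                population_filter="antidepressant_only",
            ).fit(adjusted=True)
            emit("signal_table_n06a", _signal_rows(sens.results), "signal_table")
            n_tests += sum(1 for r in sens.results if r.ror is not None)
            logger.info("stage n06a_population done in %.2fs", time.time() - t)

        if "dose" in config.analyses:
            stage = "dose"
            t = time.time()
            res = study.fit(adjusted=False)
            rows = []
            for eff in res.dose_effect(adjusted=True):
                row: dict = {"drug": eff.drug, "median_dose_mg": eff.median_dose_mg,
                             "trend_p": eff.trend_p, "evaluated": eff.evaluated}
                for side, sr in (("low", eff.low), ("high", eff.high)):
                    row[f"{side}_cases"] = None if sr is None else sr.a
                    row[f"{side}_non_cases"] = None if sr is None else sr.b
                    row[f"{side}_ror"] = None if sr is None else sr.ror
                    row[f"{side}_ci_low"] = None if sr is None else sr.ci_low
                    row[f"{side}_ci_high"] = None if sr is None else sr.ci_high
                    row[f"{side}_aror"] = None if sr is None else sr.aror
                    row[f"{side}_aci_low"] = None if sr is None else sr.aci_low
                    row[f"{side}_aci_high"] = None if sr is None else sr.aci_high
                rows.append(row)
            emit("dose_table", rows, "dose_table")
            n_tests += sum(1 for r in rows if r["evaluated"])
            logger.info("stage dose done in %.2fs", time.time() - t)

        if "descriptives" in config.analyses:
            stage = "descriptives"
            t = time.time()
            res = study.fit(adjusted=False)
            summary = res.descriptives(n_total_reports=config.n_total_reports)
            emit("cohort_summary", summary.rows(), "cohort_summary")
            cases = study.case_reports()
            from .descriptives import challenge_counts, time_to_onset

            tto_rows, chall_rows = [], []
            for drug in study.dataset.drug_labels:
                tto = time_to_onset(cases, drug, study.vocabulary)
                tto_rows.append(
                    {
                        "drug": drug,
                        "n_available": tto.n_available,
                        "median_days": tto.median_days,
                        "iqr_low_days": tto.iqr_low_days,
                        "iqr_high_days": tto.iqr_high_days,
                    }
                )
                n_de, n_re = challenge_counts(cases, drug, study.vocabulary)
                chall_rows.append(
                    {"drug": drug, "n_positive_dechallenge": n_de, "n_positive_rechallenge": n_re}
                )
            emit("tto_table", tto_rows, "tto_table")
            emit("challenge_table", chall_rows, "challenge_table")
            logger.info("stage descriptives done in %.2fs", time.time() - t)

        stage = "manifest"
        manifest = {
            "software": {"name": "pvsignal", "version": __version__},
            "config": {
                "analyses": list(config.analyses),
                "vocabulary_path": config.vocabulary_path,
                "seed": config.seed,
            },
            "config_hash": hashlib.sha256(
                repr(
                    (sorted(config.analyses), config.vocabulary_path,
                     config.n_total_reports, config.seed)
                ).encode()
            ).hexdigest(),
            "inputs": {
                "reports": _md5(config.reports_path),
                "drugs": _md5(config.drugs_path),
                "reactions": _md5(config.reactions_path),
            },
            "n_analytic_records": study.n_records,
            "row_counts": row_counts,
            "n_statistical_tests": n_tests,
            "multiple_testing_correction": "none",
        }
        manifest_path = out_dir / "manifest.yaml"
        with open(manifest_path, "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        written["manifest"] = manifest_path
    except Exception as exc:
        for path in written.values():
            raw = path.with_name(path.stem + "_raw" + path.suffix)
            for p in (path, raw):
                if p.exists():
                    p.unlink()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return written


# Calibration ----------------------------------------------------------------


def config_vocabulary(config: SyntheticConfig) -> Vocabulary:
    """Minimal vocabulary matching a synthetic config's planted structure."""
    return Vocabulary(
        smq_terms=frozenset({config.event_term}),
        target_drugs={spec.label: frozenset({spec.drug_code}) for spec in config.drug_specs},
        antihypertensive_codes=frozenset({"C02"}),
        hypertensive_inducer_codes=frozenset({"H02AB", "M01A", "L04AD", "C01CA"}),
        comparator_population_codes=frozenset({"N06A"}),
        stroke_terms=frozenset({"Cerebrovascular accident"}),
        mi_terms=frozenset({"Myocardial infarction"}),
    )


@dataclass
class CalibrationReport:
    """Replicate-level estimates against planted truth."""

    table: pd.DataFrame
    n_replicates: int

    def summary(self) -> dict:
        t = self.table
        defined = t.dropna(subset=["ror"])
        out = {
            "n_replicates": self.n_replicates,
            "n_estimates": len(defined),
            "signal_rate": float(defined["signal"].mean()) if len(defined) else float("nan"),
            "ci_coverage": float(
                ((defined["ci_low"] <= defined["true_or"]) & (defined["true_or"] <= defined["ci_high"])).mean()
            )
            if len(defined)
            else float("nan"),
            "mean_ror": float(defined["ror"].mean()) if len(defined) else float("nan"),
        }
        adj = t.dropna(subset=["aror"])
        out["mean_aror"] = float(adj["aror"].mean()) if len(adj) else float("nan")
        return out


def simulate_and_validate(
    config: SyntheticConfig,
    n_replicates: int,
    seed: int = 0,
    adjusted: bool = False,
) -> CalibrationReport:
    """Generate ``n_replicates`` databases and run the case/non-case
    estimators on each, reporting empirical signal rate, CI coverage and
    (optionally) adjusted-ROR recovery against the planted truth.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    from dataclasses import replace

    from .dataset import build_analytic_frame
    from .disproportionality import adjusted_ror

    vocab = config_vocabulary(config)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) & 0x7FFFFFFF
    rows = []
    truth = {spec.label: float(np.exp(spec.log_or)) for spec in config.drug_specs}
    for rep, child in enumerate(child_seeds):
        cfg = replace(config, seed=int(child))
        frames = generate_frames(cfg)
        dataset = build_analytic_frame(frames, vocab)
        for spec in config.drug_specs:
            table = dataset.contingency(spec.label)
            ror, lo, hi = compute_ror(table)
            aror = None
            if adjusted and ror is not None:
                aror, _, _ = adjusted_ror(dataset, spec.label)
            rows.append(
                {
                    "replicate": rep,
                    "drug": spec.label,
                    "true_or": truth[spec.label],
                    "a": table.a,
                    "b": table.b,
                    "ror": ror,
                    "ci_low": lo,
                    "ci_high": hi,
                    "signal": signal_flag(ror, lo),
                    "aror": aror,
                }
            )
    return CalibrationReport(table=pd.DataFrame(rows), n_replicates=n_replicates)
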