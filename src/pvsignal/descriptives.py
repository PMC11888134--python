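"""Cohort characterization, time-to-onset and dechallenge/rechallenge counts.

Percentage conventions follow the usual report-table structure:
seriousness-criteria percentages are computed over *serious* reports,
seriousness itself over reports with *known* seriousness, and every other
field over all cases.  Percentages are rounded half-up to one decimal and
always recompute exactly from the printed count and denominator.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

import numpy as np

from .types import (
    AGE_GROUPS,
    SERIOUSNESS_CRITERIA,
    ICSRReport,
    Vocabulary,
    canonical_term,
    code_matches,
)

__all__ = [
    "CohortSummary",
    "TTOSummary",
    "round_half_up",
    "pct",
    "summarize_cohort",
    "time_to_onset",
    "challenge_counts",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, denominator: int) -> Optional[float]:
    """Percentage rounded half-up to one decimal; None for an empty denominator."""
    if denominator == 0:
        return None
    return round_half_up(100.0 * count / denominator, 1)


@dataclass
class CohortSummary:
    """Counts and percentages characterizing the case cohort."""

    n_cases: int
    n_female: int
    pct_female: Optional[float]
    age_counts: dict[str, int]
    age_pcts: dict[str, Optional[float]]
    n_serious_known: int
    n_serious: int
    pct_serious: Optional[float]
    criteria_counts: dict[str, int]
    criteria_pcts: dict[str, Optional[float]]
    n_criteria_missing: int
    pct_criteria_missing: Optional[float]
    n_stroke: int
    pct_stroke: Optional[float]
    n_mi: int
    pct_mi: Optional[float]
    n_cvd: int
    n_antihypertensive: int
    pct_antihypertensive: Optional[float]
    n_inducer: int
    pct_inducer: Optional[float]
    prevalence_pct: Optional[float] = None

    def rows(self) -> list[dict]:
        """Long-format rows for the cohort_summary output table."""
        out = [
            {"field": "n_cases", "count": self.n_cases, "denominator": self.n_cases, "percent": None},
            {"field": "female", "count": self.n_female, "denominator": self.n_cases, "percent": self.pct_female},
        ]
        for band in AGE_GROUPS:
            out.append(
                {
                    "field": f"age_{band}",
                    "count": self.age_counts.get(band, 0),
                    "denominator": self.n_cases,
                    "percent": self.age_pcts.get(band),
                }
            )
        out.append(
            {"field": "serious", "count": self.n_serious, "denominator": self.n_serious_known, "percent": self.pct_serious}
        )
        for crit in SERIOUSNESS_CRITERIA:
            out.append(
                {
                    "field": f"criteria_{crit}",
                    "count": self.criteria_counts.get(crit, 0),
                    "denominator": self.n_serious,
                    "percent": self.criteria_pcts.get(crit),
                }
            )
        out += [
            {"field": "criteria_missing", "count": self.n_criteria_missing, "denominator": self.n_serious, "percent": self.pct_criteria_missing},
            {"field": "stroke", "count": self.n_stroke, "denominator": self.n_cases, "percent": self.pct_stroke},
            {"field": "myocardial_infarction", "count": self.n_mi, "denominator": self.n_cases, "percent": self.pct_mi},
            {"field": "cvd_linked", "count": self.n_cvd, "denominator": self.n_cases, "percent": None},
            {"field": "antihypertensive", "count": self.n_antihypertensive, "denominator": self.n_cases, "percent": self.pct_antihypertensive},
            {"field": "hypertensive_inducer", "count": self.n_inducer, "denominator": self.n_cases, "percent": self.pct_inducer},
        ]
        if self.prevalence_pct is not None:
            out.append(
                {"field": "case_prevalence", "count": self.n_cases, "denominator": None, "percent": self.prevalence_pct}
            )
        return out


@dataclass
class TTOSummary:
    """Time-to-onset summary for one drug (days)."""

    drug: str
    n_available: int
    median_days: Optional[float] = None
    iqr_low_days: Optional[float] = None
    iqr_high_days: Optional[float] = None


def summarize_cohort(
    case_reports: Iterable[ICSRReport],
    vocabulary: Vocabulary,
    n_total_reports: Optional[int] = None,
) -> CohortSummary:
    """Characterize the case cohort.

    Stroke / myocardial-infarction flags come from reaction terms matching
    the vocabulary's configurable term sets; comedication flags from ATC
    codes on the same report regardless of role.  ``n_total_reports``, when
    given, yields the case prevalence over the source population.
    """
    cases = list(case_reports)
    n = len(cases)
    n_female = sum(1 for r in cases if r.sex == "female")
    age_counts = {band: 0 for band in AGE_GROUPS}
    for r in cases:
        if r.age_group in age_counts:
            age_counts[r.age_group] += 1
    known = [r for r in cases if r.serious != "unknown"]
    serious = [r for r in known if r.serious == "yes"]
    n_known, n_serious = len(known), len(serious)
    criteria_counts = {crit: 0 for crit in SERIOUSNESS_CRITERIA}
    n_missing = 0
    for r in serious:
        if not r.seriousness_criteria:
            n_missing += 1
        for crit in r.seriousness_criteria:
            criteria_counts[crit] += 1

    def _has_term(report: ICSRReport, terms: frozenset[str]) -> bool:
        return any(canonical_term(rx.term) in terms for rx in report.reactions)

    def _has_code(report: ICSRReport, codes: frozenset[str]) -> bool:
        return any(code_matches(d.drug_code, codes) for d in report.drugs)

    n_stroke = sum(1 for r in cases if _has_term(r, vocabulary.stroke_terms))
    n_mi = sum(1 for r in cases if _has_term(r, vocabulary.mi_terms))
    n_aht = sum(1 for r in cases if _has_code(r, vocabulary.antihypertensive_codes))
    n_ind = sum(1 for r in cases if _has_code(r, vocabulary.hypertensive_inducer_codes))

    return CohortSummary(
        n_cases=n,
        n_female=n_female,
        pct_female=pct(n_female, n),
        age_counts=age_counts,
        age_pcts={band: pct(cnt, n) for band, cnt in age_counts.items()},
        n_serious_known=n_known,
        n_serious=n_serious,
        pct_serious=pct(n_serious, n_known),
        criteria_counts=criteria_counts,
        criteria_pcts={c: pct(v, n_serious) for c, v in criteria_counts.items()},
        n_criteria_missing=n_missing,
        pct_criteria_missing=pct(n_missing, n_serious),
        n_stroke=n_stroke,
        pct_stroke=pct(n_stroke, n),
        n_mi=n_mi,
        pct_mi=pct(n_mi, n),
        n_cvd=n_stroke + n_mi,
        n_antihypertensive=n_aht,
        pct_antihypertensive=pct(n_aht, n),
        n_inducer=n_ind,
        pct_inducer=pct(n_ind, n),
        prevalence_pct=None if n_total_reports is None else pct(n, n_total_reports),
    )


def _report_tto(report: ICSRReport, drug_codes: frozenset[str], smq_terms: frozenset[str]) -> Optional[int]:
    """Whole-day onset latency for one report, or None when not computable.

    Latency = earliest matching-reaction onset date minus the drug's start
    date (earliest matching entry with a start date).  Negative latencies
    indicate data errors and are excluded rather than clamped.
    """
    starts = [
        d.start_date
        for d in report.drugs
        if d.start_date is not None and code_matches(d.drug_code, drug_codes)
    ]
    onsets = [
        rx.onset_date
        for rx in report.reactions
        if rx.onset_date is not None and canonical_term(rx.term) in smq_terms
    ]
    if not starts or not onsets:
        return None
    tto = (min(onsets) - min(starts)).days
    return tto if tto >= 0 else None


def time_to_onset(
    case_reports: Iterable[ICSRReport],
    drug: str,
    vocabulary: Vocabulary,
) -> TTOSummary:
    """Median and interquartile range of onset latency for one drug.

    Only case reports exposed to the drug with both a drug start date and a
    matching-reaction onset date contribute.  Quartiles use midpoint
    interpolation.  With no usable report the summary is undefined (NA).
    """
    codes = vocabulary.target_drugs[drug]
    values = []
    for r in case_reports:
        tto = _report_tto(r, codes, vocabulary.smq_terms)
        if tto is not None:
            values.append(tto)
    if not values:
        return TTOSummary(drug=drug, n_available=0)
    arr = np.asarray(values, dtype=float)
    return TTOSummary(
        drug=drug,
        n_available=len(values),
        median_days=float(np.percentile(arr, 50, method="midpoint")),
        iqr_low_days=float(np.percentile(arr, 25, method="midpoint")),
        iqr_high_days=float(np.percentile(arr, 75, method="midpoint")),
    )


def challenge_counts(
    case_reports: Iterable[ICSRReport],
    drug: str,
    vocabulary: Vocabulary,
) -> tuple[int, int]:
    """Positive dechallenge / rechallenge counts for one drug.

    A report counts once per drug when any matching entry records the
    positive outcome, independently for each field.
    """
    codes = vocabulary.target_drugs[drug]
    n_de = n_re = 0
    for r in case_reports:
        entries = [d for d in r.drugs if code_matches(d.drug_code, codes)]
        if not entries:
            continue
        if any(d.dechallenge == "positive" for d in entries):
            n_de += 1
        if any(d.rechallenge == "positive" for d in entries):
            n_re += 1
    return n_de, n_re
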