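"""Dose-effect exploration: median split, stratified RORs, trend test.

For each drug the recorded daily doses of exposed reports (cases and
non-cases alike) are split at their median: the low stratum takes doses
less than or equal to the median (ties go low), the high stratum doses
above it.  Each stratum is compared against the same unexposed reports as
the main analysis, with crude and adjusted RORs; exposed reports with no
recorded dose contribute to neither stratum.  A stratum pair is evaluated
only when both strata hold at least five exposed cases; otherwise every
stratified field is undefined.  The dose trend is tested by an ordinary
least-squares regression of case status on the high-stratum indicator over
the drug's exposed, dose-recorded reports (two-sided slope p-value).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .dataset import AnalyticDataset, contingency_from_masks
from .disproportionality import adjusted_ror, compute_ror, signal_flag
from .types import SignalResult

__all__ = ["DoseEffectResult", "median_dose", "stratified_analysis", "trend_test"]

MIN_CASES_PER_STRATUM = 5


@dataclass
class DoseEffectResult:
    """Median-split dose analysis for one drug."""

    drug: str
    median_dose_mg: Optional[float]
    low: Optional[SignalResult]
    high: Optional[SignalResult]
    trend_p: Optional[float]
    evaluated: bool


def median_dose(dataset: AnalyticDataset, drug: str) -> Optional[float]:
    """Median recorded daily dose over the drug's exposed reports.

    Uses cases and non-cases together; an even count returns the mean of
    the two central values.  ``None`` when no exposed report has a recorded
    dose (the dose analysis is then skipped for that drug).
    """
    exposed = dataset.exposure_mask(drug)
    doses = dataset.dose_values(drug)[exposed]
    doses = doses[~np.isnan(doses)]
    if doses.size == 0:
        return None
    return float(np.median(doses))


def trend_test(dataset: AnalyticDataset, drug: str) -> Optional[float]:
    """Two-sided p-value of the OLS slope of case status on the stratum
    indicator (0 = dose <= median, 1 = dose > median) over exposed,
    dose-recorded reports.  ``None`` when the indicator has no variance.
    """
    med = median_dose(dataset, drug)
    if med is None:
        return None
    exposed = dataset.exposure_mask(drug)
    doses = dataset.dose_values(drug)
    mask = exposed & ~np.isnan(doses)
    x = (doses[mask] > med).astype(float)
    y = dataset.case_mask()[mask].astype(float)
    if x.size < 3 or x.min() == x.max():
        return None
    res = stats.linregress(x, y)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def _stratum_result(
    dataset: AnalyticDataset,
    drug: str,
    stratum_exposed: np.ndarray,
    unexposed: np.ndarray,
    adjusted: bool,
) -> SignalResult:
    case = dataset.case_mask()
    keep = stratum_exposed | unexposed
    table = contingency_from_masks(case[keep], stratum_exposed[keep])
    ror, lo, hi = compute_ror(table)
    aror = alo = ahi = None
    if adjusted and ror is not None:
        aror, alo, ahi = adjusted_ror(
            dataset, drug, exposed=stratum_exposed, subset=keep
        )
    return SignalResult(
        drug=drug,
        a=table.a,
        b=table.b,
        ror=ror,
        ci_low=lo,
        ci_high=hi,
        aror=aror,
        aci_low=alo,
        aci_high=ahi,
        signal=signal_flag(ror, lo),
    )


def stratified_analysis(
    dataset: AnalyticDataset,
    drug: str,
    adjusted: bool = True,
    min_cases: int = MIN_CASES_PER_STRATUM,
) -> DoseEffectResult:
    """Median-split stratified analysis for one drug.

    Both strata share the main analysis' unexposed comparator cells;
    stratification applies only to exposed reports.  When either stratum
    has fewer than ``min_cases`` exposed cases the result is not evaluated
    and all stratified fields are undefined.
    """
    med = median_dose(dataset, drug)
    if med is None:
        return DoseEffectResult(
            drug=drug, median_dose_mg=None, low=None, high=None, trend_p=None, evaluated=False
        )
    exposed = dataset.exposure_mask(drug)
    doses = dataset.dose_values(drug)
    recorded = exposed & ~np.isnan(doses)
    low_exposed = recorded & (doses <= med)
    high_exposed = recorded & (doses > med)
    unexposed = ~exposed
    case = dataset.case_mask()
    a_low = int(np.sum(low_exposed & case))
    a_high = int(np.sum(high_exposed & case))
    if a_low < min_cases or a_high < min_cases:
        return DoseEffectResult(
            drug=drug, median_dose_mg=med, low=None, high=None, trend_p=None, evaluated=False
        )
    low = _stratum_result(dataset, drug, low_exposed, unexposed, adjusted)
    high = _stratum_result(dataset, drug, high_exposed, unexposed, adjusted)
    return DoseEffectResult(
        drug=drug,
        median_dose_mg=med,
        low=low,
        high=high,
        trend_p=trend_test(dataset, drug),
        evaluated=True,
    )
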