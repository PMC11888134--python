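"""Reporting odds ratio, signal rule, and covariate-adjusted ROR.

The crude ROR for a 2x2 drug-event table is (a*d)/(b*c) with a log-normal
(Woolf) 95% confidence interval,

    exp( ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d) ),  z = 1.959964.

A disproportionality signal is declared when ROR > 1 and the lower CI bound
exceeds 1 (both strict).  Adjusted RORs come from a multivariable logistic
model of case status on the exposure indicator plus age band, sex,
concurrent-antihypertensive and pressor-comedication flags, fitted by
iteratively reweighted least squares (Newton scoring); the aROR is the
exponentiated exposure coefficient with a Wald interval.

For a saturated 2x2 logistic model the exponentiated slope equals (ad)/(bc)
and its Wald interval equals the Woolf interval exactly; that identity is
used as a cross-check in the test-suite, with an independent fitter as
oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .dataset import CLASS_LABEL, AnalyticDataset
from .types import ContingencyTable, SignalResult, Vocabulary, code_matches

Z_95 = 1.959964

__all__ = [
    "Z_95",
    "compute_ror",
    "signal_flag",
    "fit_logistic",
    "LogisticFit",
    "adjusted_ror",
    "signal_results",
]


def compute_ror(
    table: ContingencyTable,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Crude reporting odds ratio with Woolf 95% CI.

    A drug with no exposed case (``a == 0``) or no exposed report at all has
    an undefined ROR and returns ``(None, None, None)``.  When any other
    cell is zero the Haldane-Anscombe continuity correction (+0.5 on all
    four cells) is applied before estimation.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if a == 0 or a + b == 0:
        return None, None, None
    fa, fb, fc, fd = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        fa, fb, fc, fd = fa + 0.5, fb + 0.5, fc + 0.5, fd + 0.5
    ror = (fa * fd) / (fb * fc)
    se = np.sqrt(1.0 / fa + 1.0 / fb + 1.0 / fc + 1.0 / fd)
    log_ror = np.log(ror)
    return (
        float(ror),
        float(np.exp(log_ror - Z_95 * se)),
        float(np.exp(log_ror + Z_95 * se)),
    )


def signal_flag(ror: Optional[float], ci_low: Optional[float]) -> Optional[bool]:
    """Signal rule: ROR > 1 and lower 95% bound > 1, both strict.

    Undefined inputs give an undefined flag (``None``).
    """
    if ror is None or ci_low is None:
        return None
    return bool(ror > 1.0 and ci_low > 1.0)


# Logistic regression (IRLS) -------------------------------------------------


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit."""

    params: np.ndarray
    bse: np.ndarray
    converged: bool
    separation: bool
    n_iter: int
    column_names: list[str]

    @property
    def ok(self) -> bool:
        return self.converged and not self.separation


def fit_logistic(
    outcome: np.ndarray,
    design_matrix: np.ndarray,
    weights: Optional[np.ndarray] = None,
    column_names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Logistic regression by iteratively reweighted least squares.

    ``weights`` are optional frequency weights (grouped data).  Convergence
    is declared when the largest absolute coefficient change falls below
    ``tol``.  Complete or quasi-complete separation — some fitted
    probability within 1e-10 of 0 or 1 together with a diverging
    coefficient — is flagged rather than silently returned.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design matrix and outcome are incompatible")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    n, p = X.shape
    names = list(column_names) if column_names is not None else [f"x{j}" for j in range(p)]

    beta = np.zeros(p)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        wls = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu))
        info = (X * wls[:, None]).T @ X
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, grad, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
    extreme = np.any((mu < 1e-10) | (mu > 1.0 - 1e-10))
    separation = bool(extreme and np.max(np.abs(beta)) > 15.0) or (
        not converged and extreme
    )
    wls = np.clip(w * mu * (1.0 - mu), 1e-300, None)
    info = (X * wls[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse = np.full(p, np.nan)
    return LogisticFit(
        params=beta,
        bse=bse,
        converged=converged,
        separation=separation,
        n_iter=n_iter,
        column_names=names,
    )


def _covariate_flags_excluding(
    dataset: AnalyticDataset, drug: str
) -> tuple[np.ndarray, np.ndarray]:
    """Antihypertensive / pressor-comedication flags for the adjusted model.

    The target drug is never counted in its own covariate: if the drug's
    codes overlap a covariate code set, the flag is recomputed from the
    non-target entries.  With disjoint code sets (the usual situation) the
    precomputed columns are returned unchanged.
    """
    vocab: Vocabulary = dataset.vocabulary
    aht = dataset.df["has_antihypertensive"].to_numpy()
    ind = dataset.df["has_inducer"].to_numpy()
    if drug == CLASS_LABEL:
        return aht, ind
    own = vocab.target_drugs[drug]
    overlap_aht = any(code_matches(c, vocab.antihypertensive_codes) for c in own)
    overlap_ind = any(code_matches(c, vocab.hypertensive_inducer_codes) for c in own)
    if overlap_aht:
        aht = aht & ~dataset.exposure_mask(drug)
    if overlap_ind:
        ind = ind & ~dataset.exposure_mask(drug)
    return aht, ind


def build_design(
    dataset: AnalyticDataset,
    exposed: np.ndarray,
    subset: Optional[np.ndarray] = None,
    drug: str = CLASS_LABEL,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the adjusted model.

    Columns: intercept, exposure, age-band dummies (reference 18-44), sex
    dummies (reference female; ``unknown`` kept as its own level), the two
    comedication flags.  Constant columns are dropped so degenerate inputs
    (e.g. a single age band) reduce gracefully toward the crude model.
    """
    df = dataset.df
    aht, ind = _covariate_flags_excluding(dataset, drug)
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(df)))]
    cols.append(("exposure", exposed.astype(float)))
    age = df["age_group"].to_numpy()
    for band in ("45-64", "65-74", "75plus"):
        cols.append((f"age_{band}", (age == band).astype(float)))
    sex = df["sex"].to_numpy()
    cols.append(("sex_male", (sex == "male").astype(float)))
    cols.append(("sex_unknown", (sex == "unknown").astype(float)))
    cols.append(("antihypertensive", aht.astype(float)))
    cols.append(("inducer", ind.astype(float)))

    if subset is not None:
        cols = [(name, col[subset]) for name, col in cols]
    kept_names, kept = [], []
    for name, col in cols:
        if name in ("intercept", "exposure") or col.min() != col.max():
            kept_names.append(name)
            kept.append(col)
    return np.column_stack(kept), kept_names


def adjusted_ror(
    dataset: AnalyticDataset,
    drug: str,
    exposed: Optional[np.ndarray] = None,
    subset: Optional[np.ndarray] = None,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Covariate-adjusted ROR for one drug (or the pooled class).

    Returns ``(None, None, None)`` when there is no exposed case or when
    the logistic fit fails to converge / separates.  ``exposed`` and
    ``subset`` allow dose-stratified calls that replace the exposure
    indicator and restrict the record set.
    """
    if exposed is None:
        exposed = dataset.exposure_mask(drug)
    y = dataset.case_mask()
    if subset is not None:
        y_fit = y[subset]
        exp_fit = exposed[subset]
    else:
        y_fit = y
        exp_fit = exposed
    if int(np.sum(exp_fit & y_fit)) < 1 or int(np.sum(exp_fit)) == len(exp_fit):
        return None, None, None
    X, names = build_design(dataset, exposed, subset=subset, drug=drug)
    fit = fit_logistic(y_fit, X, column_names=names)
    if not fit.ok:
        return None, None, None
    j = names.index("exposure")
    coef, se = fit.params[j], fit.bse[j]
    if not np.isfinite(coef) or not np.isfinite(se) or se == 0:
        return None, None, None
    return (
        float(np.exp(coef)),
        float(np.exp(coef - Z_95 * se)),
        float(np.exp(coef + Z_95 * se)),
    )


def signal_results(
    dataset: AnalyticDataset,
    adjusted: bool = True,
    include_class: bool = True,
) -> list[SignalResult]:
    """Per-drug signal table rows (alphabetical) plus the pooled class row.

    The class row's ``a`` counts case reports exposed to at least one target
    drug, not the sum of per-drug cells (which would double-count
    co-exposed reports).
    """
    drugs = list(dataset.drug_labels)
    if include_class:
        drugs.append(CLASS_LABEL)
    out = []
    for drug in drugs:
        table = dataset.contingency(drug)
        ror, lo, hi = compute_ror(table)
        aror = alo = ahi = None
        if adjusted and ror is not None:
            aror, alo, ahi = adjusted_ror(dataset, drug)
        out.append(
            SignalResult(
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
        )
    return out
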