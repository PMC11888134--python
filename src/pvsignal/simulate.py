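"""Synthetic ICSR database generator with known ground truth.

The generator emulates the structure of a spontaneous-report extract: each
report carries demographic covariates, drug entries (with role, dose, start
date and dechallenge/rechallenge outcomes) and reaction terms.  Case status
is drawn from a logistic model

    logit P(case) = baseline + sum_j exposure_j * log_or_j + covariate effects

so every reporting odds ratio the analysis estimates has a planted truth.
Exposure probabilities can be tilted by the same covariate score that drives
the event (``exposure_confounding_log_or``), which creates genuine
confounding for the adjusted analysis to remove.

Random-number streams are split per component (covariates, outcomes, dates,
misc, and one stream per drug) so adding a drug does not perturb the draws
of the others.  ``generate_frames`` is a pure function of its config,
including the seed.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .io import DRUG_COLUMNS, REACTION_COLUMNS, REPORT_COLUMNS, ICSRFrames, frames_to_reports, write_frames
from .types import AGE_GROUPS, ICSRReport

__all__ = [
    "DrugSpec",
    "ConfounderSpec",
    "SyntheticConfig",
    "generate_frames",
    "generate_database",
    "make_paper_like_config",
    "write_synthetic_database",
]


class ConfigError(ValueError):
    """Invalid synthetic-database configuration."""


def _check_prob(name: str, p: float, open_interval: bool = False) -> None:
    lo_ok = p > 0 if open_interval else p >= 0
    hi_ok = p < 1 if open_interval else p <= 1
    if not (lo_ok and hi_ok):
        raise ConfigError(f"{name}={p} outside the valid probability range")


@dataclass
class DrugSpec:
    """Planted behaviour of one target drug."""

    drug_code: str
    label: str
    exposure_prevalence: float
    log_or: float = 0.0
    dose_median_mg: float = 50.0
    dose_dispersion: float = 0.4

    def __post_init__(self) -> None:
        _check_prob(f"exposure_prevalence[{self.label}]", self.exposure_prevalence, open_interval=True)
        if self.dose_median_mg <= 0 or self.dose_dispersion <= 0:
            raise ConfigError("dose_median_mg and dose_dispersion must be positive")


@dataclass
class ConfounderSpec:
    """Covariate distribution and covariate effects on the event log-odds.

    ``log_or_age`` is keyed by age band with 18-44 as the implicit reference;
    ``log_or_sex`` applies to male (female is the reference).
    ``exposure_confounding_log_or`` multiplies the covariate score when
    tilting each drug's exposure probability (0 means no confounding).
    """

    age_distribution: dict[str, float] = field(
        default_factory=lambda: {"18-44": 0.40, "45-64": 0.35, "65-74": 0.15, "75plus": 0.10}
    )
    p_female: float = 0.60
    p_antihypertensive: float = 0.05
    p_hypertensive_inducer: float = 0.20
    log_or_age: dict[str, float] = field(default_factory=dict)
    log_or_sex: float = 0.0
    log_or_antihypertensive: float = 0.0
    log_or_inducer: float = 0.0
    exposure_confounding_log_or: float = 0.0

    def __post_init__(self) -> None:
        missing = set(AGE_GROUPS) - set(self.age_distribution)
        if missing:
            raise ConfigError(f"age_distribution missing bands {sorted(missing)}")
        total = sum(self.age_distribution.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ConfigError("age_distribution must sum to 1")
        _check_prob("p_female", self.p_female, open_interval=True)
        _check_prob("p_antihypertensive", self.p_antihypertensive)
        _check_prob("p_hypertensive_inducer", self.p_hypertensive_inducer)


@dataclass
class SyntheticConfig:
    """Full parameterization of one synthetic report database."""

    n_reports: int
    baseline_event_logit: float
    drug_specs: list[DrugSpec]
    confounders: ConfounderSpec = field(default_factory=ConfounderSpec)
    tto_mean_days: float = 30.0
    p_dechallenge_positive: float = 0.30
    p_rechallenge_positive: float = 0.02
    p_serious: float = 0.60
    p_dose_missing: float = 0.80
    p_age_unknown: float = 0.0
    p_sex_unknown: float = 0.0
    p_suspect_role: float = 0.60
    p_other_antidepressant: float = 0.05
    p_stroke_term: float = 0.0
    p_mi_term: float = 0.0
    event_term: str = "Hypertension"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ConfigError("n_reports must be non-negative")
        if self.tto_mean_days <= 0:
            raise ConfigError("tto_mean_days must be positive")
        codes = [d.drug_code for d in self.drug_specs]
        if len(codes) != len(set(codes)):
            raise ConfigError("drug codes must be unique")
        for name in (
            "p_dechallenge_positive",
            "p_rechallenge_positive",
            "p_serious",
            "p_dose_missing",
            "p_age_unknown",
            "p_sex_unknown",
            "p_suspect_role",
            "p_other_antidepressant",
            "p_stroke_term",
            "p_mi_term",
        ):
            _check_prob(name, getattr(self, name))


_BACKGROUND_TERMS = ("Nausea", "Headache", "Dizziness", "Rash", "Insomnia", "Fatigue")
_STROKE_TERM = "Cerebrovascular accident"
_MI_TERM = "Myocardial infarction"
_AHT_CODE = "C02AC01"
_INDUCER_CODES = ("H02AB06", "M01AE01", "L04AD01", "C01CA04")
_OTHER_ANTIDEPRESSANT_CODE = "N06AX16"
_BACKGROUND_DRUG_CODE = "A02BC01"
_BASE_DATE = np.datetime64("2010-01-01")
_CRITERIA_CHOICES = ("hospitalization", "death", "life_threatening", "disabling", "other", "")
_CRITERIA_PROBS = (0.42, 0.07, 0.05, 0.03, 0.30, 0.13)


def _empty_frames() -> ICSRFrames:
    return ICSRFrames(
        reports=pd.DataFrame(columns=REPORT_COLUMNS),
        drugs=pd.DataFrame(columns=DRUG_COLUMNS),
        reactions=pd.DataFrame(columns=REACTION_COLUMNS),
    )


def generate_frames(config: SyntheticConfig) -> ICSRFrames:
    """Draw one database as the three relational tables.

    Deterministic for a given config: the same seed yields byte-identical
    tables when written to disk.
    """
    n = config.n_reports
    if n == 0:
        return _empty_frames()
    conf = config.confounders

    root = np.random.SeedSequence(config.seed)
    cov_ss, out_ss, date_ss, misc_ss, drug_parent = root.spawn(5)
    rng_cov = np.random.default_rng(cov_ss)
    rng_out = np.random.default_rng(out_ss)
    rng_date = np.random.default_rng(date_ss)
    rng_misc = np.random.default_rng(misc_ss)
    drug_seeds = drug_parent.spawn(len(config.drug_specs))

    report_ids = np.array([f"R{i:07d}" for i in range(n)])

    # Covariates -----------------------------------------------------------
    bands = np.array(AGE_GROUPS)
    p_age = np.array([conf.age_distribution[b] for b in AGE_GROUPS], dtype=float)
    p_age = p_age / p_age.sum()
    age_idx = rng_cov.choice(len(bands), size=n, p=p_age)
    female = rng_cov.random(n) < conf.p_female
    has_aht = rng_cov.random(n) < conf.p_antihypertensive
    has_ind = rng_cov.random(n) < conf.p_hypertensive_inducer
    age_unknown = rng_cov.random(n) < config.p_age_unknown
    sex_unknown = rng_cov.random(n) < config.p_sex_unknown

    age_or = np.array([conf.log_or_age.get(b, 0.0) for b in AGE_GROUPS])
    eta_cov = (
        age_or[age_idx]
        + (~female) * conf.log_or_sex
        + has_aht * conf.log_or_antihypertensive
        + has_ind * conf.log_or_inducer
    )

    # Exposures (per-drug streams) ----------------------------------------
    c = conf.exposure_confounding_log_or
    exposed = np.zeros((len(config.drug_specs), n), dtype=bool)
    drug_rngs = []
    for j, (spec, dss) in enumerate(zip(config.drug_specs, drug_seeds)):
        rng_j = np.random.default_rng(dss)
        drug_rngs.append(rng_j)
        p_j = expit(logit(spec.exposure_prevalence) + c * eta_cov)
        exposed[j] = rng_j.random(n) < p_j

    # Outcome --------------------------------------------------------------
    log_ors = np.array([spec.log_or for spec in config.drug_specs])
    eta = config.baseline_event_logit + eta_cov + log_ors @ exposed
    event = rng_out.random(n) < expit(eta)

    # Drug entries ---------------------------------------------------------
    id_col, code_col, role_col = [], [], []
    dose_col, start_col, stop_col, de_col, re_col = [], [], [], [], []
    anchor_start = np.full(n, np.nan)  # days since base date of first exposed drug
    has_entry = np.zeros(n, dtype=bool)

    role_levels = np.array(["suspect", "concomitant", "interacting"])
    for spec, rng_j, exp_j in zip(config.drug_specs, drug_rngs, exposed):
        idx = np.flatnonzero(exp_j)
        m = len(idx)
        if m == 0:
            continue
        u_role = rng_j.random(m)
        p_s = config.p_suspect_role
        roles = np.where(
            u_role < p_s,
            "suspect",
            np.where(u_role < p_s + 0.85 * (1 - p_s), "concomitant", "interacting"),
        )
        start_days = rng_j.integers(0, 5000, size=m).astype(float)
        has_stop = rng_j.random(m) < 0.5
        stop_days = np.where(has_stop, start_days + rng_j.integers(7, 365, size=m), np.nan)
        dose = spec.dose_median_mg * np.exp(spec.dose_dispersion * rng_j.standard_normal(m))
        dose[rng_j.random(m) < config.p_dose_missing] = np.nan

        ev = event[idx]
        u_de = rng_j.random(m)
        de = np.where(
            ev & (u_de < config.p_dechallenge_positive),
            "positive",
            np.where(ev & (u_de < config.p_dechallenge_positive + 0.2), "negative", "unknown"),
        )
        u_re = rng_j.random(m)
        re = np.where(
            ev & (u_re < config.p_rechallenge_positive),
            "positive",
            np.where(ev & (u_re < 2 * config.p_rechallenge_positive), "negative", "not_done"),
        )

        id_col.append(report_ids[idx])
        code_col.append(np.full(m, spec.drug_code))
        role_col.append(roles)
        dose_col.append(dose)
        start_col.append(start_days)
        stop_col.append(stop_days)
        de_col.append(de)
        re_col.append(re)

        fresh = np.isnan(anchor_start[idx])
        anchor_start[idx[fresh]] = start_days[fresh]
        has_entry[idx] = True

    def _plain_entries(idx: np.ndarray, code: str, role: str) -> None:
        m = len(idx)
        if m == 0:
            return
        id_col.append(report_ids[idx])
        code_col.append(np.full(m, code))
        role_col.append(np.full(m, role))
        dose_col.append(np.full(m, np.nan))
        start_col.append(np.full(m, np.nan))
        stop_col.append(np.full(m, np.nan))
        de_col.append(np.full(m, "unknown"))
        re_col.append(np.full(m, "not_done"))

    _plain_entries(np.flatnonzero(has_aht), _AHT_CODE, "concomitant")
    idx_ind = np.flatnonzero(has_ind)
    if len(idx_ind):
        codes = np.array(_INDUCER_CODES)[rng_misc.integers(0, len(_INDUCER_CODES), len(idx_ind))]
        id_col.append(report_ids[idx_ind])
        code_col.append(codes)
        role_col.append(np.full(len(idx_ind), "concomitant"))
        dose_col.append(np.full(len(idx_ind), np.nan))
        start_col.append(np.full(len(idx_ind), np.nan))
        stop_col.append(np.full(len(idx_ind), np.nan))
        de_col.append(np.full(len(idx_ind), "unknown"))
        re_col.append(np.full(len(idx_ind), "not_done"))
        has_entry[idx_ind] = True
    has_entry[np.flatnonzero(has_aht)] = True
    other_ad = rng_misc.random(n) < config.p_other_antidepressant
    _plain_entries(np.flatnonzero(other_ad), _OTHER_ANTIDEPRESSANT_CODE, "concomitant")
    has_entry[other_ad] = True

    # Every report carries at least one drug; reports with no entry so far
    # get a background (non-target, non-covariate) suspect drug with a start
    # date so that unexposed cases still have a plausible onset anchor.
    idx_bg = np.flatnonzero(~has_entry)
    if len(idx_bg):
        bg_start = rng_misc.integers(0, 5000, size=len(idx_bg)).astype(float)
        id_col.append(report_ids[idx_bg])
        code_col.append(np.full(len(idx_bg), _BACKGROUND_DRUG_CODE))
        role_col.append(np.full(len(idx_bg), "suspect"))
        dose_col.append(np.full(len(idx_bg), np.nan))
        start_col.append(bg_start)
        stop_col.append(np.full(len(idx_bg), np.nan))
        de_col.append(np.full(len(idx_bg), "unknown"))
        re_col.append(np.full(len(idx_bg), "not_done"))
        anchor_fresh = np.isnan(anchor_start[idx_bg])
        anchor_start[idx_bg[anchor_fresh]] = bg_start[anchor_fresh]

    def _days_to_dates(days: np.ndarray) -> pd.Series:
        out = pd.Series(pd.NaT, index=range(len(days)), dtype="datetime64[ns]")
        ok = ~np.isnan(days)
        out[ok] = pd.to_datetime(_BASE_DATE) + pd.to_timedelta(days[ok].astype(int), unit="D")
        return out

    drugs_df = pd.DataFrame(
        {
            "report_id": np.concatenate(id_col),
            "drug_code": np.concatenate(code_col),
            "role": np.concatenate(role_col),
            "daily_dose_mg": np.concatenate(dose_col),
            "start_date": _days_to_dates(np.concatenate(start_col)).values,
            "stop_date": _days_to_dates(np.concatenate(stop_col)).values,
            "dechallenge": np.concatenate(de_col),
            "rechallenge": np.concatenate(re_col),
        }
    )

    # Reactions ------------------------------------------------------------
    rx_ids, rx_terms, rx_onset = [], [], []
    idx_event = np.flatnonzero(event)
    tto = np.floor(rng_date.exponential(config.tto_mean_days, size=len(idx_event)))
    onset_days = anchor_start[idx_event] + tto  # NaN anchor -> missing onset
    rx_ids.append(report_ids[idx_event])
    rx_terms.append(np.full(len(idx_event), config.event_term))
    rx_onset.append(onset_days)

    stroke = event & (rng_misc.random(n) < config.p_stroke_term)
    mi = event & (rng_misc.random(n) < config.p_mi_term)
    for extra_idx, term in ((np.flatnonzero(stroke), _STROKE_TERM), (np.flatnonzero(mi), _MI_TERM)):
        if len(extra_idx):
            rx_ids.append(report_ids[extra_idx])
            rx_terms.append(np.full(len(extra_idx), term))
            rx_onset.append(np.full(len(extra_idx), np.nan))

    idx_noncase = np.flatnonzero(~event)
    bg_terms = np.array(_BACKGROUND_TERMS)[
        rng_misc.integers(0, len(_BACKGROUND_TERMS), len(idx_noncase))
    ]
    rx_ids.append(report_ids[idx_noncase])
    rx_terms.append(bg_terms)
    rx_onset.append(np.full(len(idx_noncase), np.nan))

    reactions_df = pd.DataFrame(
        {
            "report_id": np.concatenate(rx_ids),
            "term": np.concatenate(rx_terms),
            "onset_date": _days_to_dates(np.concatenate(rx_onset)).values,
        }
    ).sort_values("report_id", kind="stable", ignore_index=True)

    # Reports --------------------------------------------------------------
    u_ser = rng_misc.random(n)
    serious = np.where(
        u_ser < config.p_serious,
        "yes",
        np.where(u_ser < config.p_serious + 0.8 * (1 - config.p_serious), "no", "unknown"),
    )
    crit_draw = rng_misc.choice(len(_CRITERIA_CHOICES), size=n, p=_CRITERIA_PROBS)
    criteria = np.where(
        serious == "yes", np.array(_CRITERIA_CHOICES, dtype=object)[crit_draw], ""
    )

    age_group = bands[age_idx].astype(object)
    age_group[age_unknown] = "unknown"
    sex = np.where(female, "female", "male").astype(object)
    sex[sex_unknown] = "unknown"

    reports_df = pd.DataFrame(
        {
            "report_id": report_ids,
            "age_group": age_group,
            "sex": sex,
            "serious": serious,
            "seriousness_criteria": criteria,
        }
    )
    drugs_df = drugs_df.sort_values("report_id", kind="stable", ignore_index=True)
    return ICSRFrames(reports=reports_df, drugs=drugs_df, reactions=reactions_df)


def generate_database(config: SyntheticConfig) -> list[ICSRReport]:
    """Generate a database as joined :class:`ICSRReport` objects."""
    return frames_to_reports(generate_frames(config))


def write_synthetic_database(config: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the three CSV tables plus ``truth.yaml`` with every planted parameter."""
    paths = write_frames(generate_frames(config), out_dir)
    truth_path = Path(out_dir) / "truth.yaml"
    with open(truth_path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
    paths["truth"] = truth_path
    return paths


# Study-scale default configuration -----------------------------------------

#: Per-drug planted structure at full scale (n_reports = 1e6): label,
#: ATC code, exposure prevalence, conditional log-odds-ratio, typical
#: daily-dose median (mg).  Prevalences put the expected exposed-report
#: counts on the scale of a large antidepressant pharmacovigilance extract;
#: conditional effects are in the range seen for adjusted reporting odds
#: ratios of this drug class (roughly 1.2-1.4, with one inactive and one
#: inverse-association drug).
_STUDY_DRUGS: list[tuple[str, str, float, float, float]] = [
    ("alaproclate", "N06AB07", 2e-6, 0.0, 200.0),
    ("citalopram", "N06AB04", 0.1155, math.log(1.16), 20.0),
    ("escitalopram", "N06AB10", 0.1117, math.log(1.25), 10.0),
    ("etoperidone", "N06AB09", 3.4e-5, 0.0, 50.0),
    ("fluoxetine", "N06AB03", 0.1281, math.log(1.29), 20.0),
    ("fluvoxamine", "N06AB08", 0.0129, math.log(0.99), 100.0),
    ("paroxetine", "N06AB05", 0.1013, math.log(1.40), 20.0),
    ("sertraline", "N06AB06", 0.1697, math.log(1.30), 50.0),
    ("zimeldine", "N06AB02", 9.2e-4, math.log(0.59), 200.0),
]

#: Baseline event log-odds at reference covariates, solved once (by
#: simulation at n = 1e6) so that the marginal case rate among exposed
#: reports is ~2.2% under the covariate mix and effects below.
_STUDY_BASELINE_LOGIT = -4.64


def make_paper_like_config(scale: float = 0.1, seed: int = 0) -> SyntheticConfig:
    """Default study-scale configuration.

    At ``scale=1`` the database holds one million reports with per-drug
    exposed-report counts on the order of a large real-world serotonin
    reuptake inhibitor extract; the default ``scale=0.1`` (100,000 reports)
    keeps desk runtimes low while preserving all rates.  ``scale`` rescales
    only the database size, never the planted rates or effects.
    """
    if scale <= 0:
        raise ConfigError("scale must be positive")
    drug_specs = [
        DrugSpec(
            drug_code=code,
            label=label,
            exposure_prevalence=prev,
            log_or=lor,
            dose_median_mg=dose,
            dose_dispersion=0.4,
        )
        for label, code, prev, lor, dose in _STUDY_DRUGS
    ]
    confounders = ConfounderSpec(
        age_distribution={"18-44": 0.40, "45-64": 0.35, "65-74": 0.15, "75plus": 0.10},
        p_female=0.60,
        p_antihypertensive=0.05,
        p_hypertensive_inducer=0.25,
        log_or_age={"45-64": 0.35, "65-74": 0.55, "75plus": 0.65},
        log_or_sex=-0.15,
        log_or_antihypertensive=1.10,
        log_or_inducer=0.55,
        exposure_confounding_log_or=0.25,
    )
    return SyntheticConfig(
        n_reports=int(round(1_000_000 * scale)),
        baseline_event_logit=_STUDY_BASELINE_LOGIT,
        drug_specs=drug_specs,
        confounders=confounders,
        tto_mean_days=30.0,
        p_dechallenge_positive=0.30,
        p_rechallenge_positive=0.02,
        p_serious=0.60,
        p_dose_missing=0.80,
        p_age_unknown=0.02,
        p_sex_unknown=0.02,
        p_stroke_term=0.07,
        p_mi_term=0.055,
        seed=seed,
    )
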