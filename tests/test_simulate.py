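import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import pvsignal as pv
from pvsignal.dataset import CLASS_LABEL, build_analytic_frame
from pvsignal.pipeline import config_vocabulary
from pvsignal.simulate import ConfigError

from conftest import null_config


class TestContract:
    def test_same_seed_identical(self, tmp_path):
        cfg = null_config(n_reports=500, seed=42)
        p1 = pv.write_synthetic_database(cfg, tmp_path / "a")
        p2 = pv.write_synthetic_database(cfg, tmp_path / "b")
        for name in ("reports", "drugs", "reactions"):
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seed_differs(self):
        f1 = pv.generate_frames(null_config(n_reports=500, seed=1))
        f2 = pv.generate_frames(null_config(n_reports=500, seed=2))
        assert not f1.reports.equals(f2.reports)

    def test_zero_reports_empty_database(self):
        assert pv.generate_database(null_config(n_reports=0)) == []

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            null_config(p_serious=1.5)
        with pytest.raises(ConfigError):
            null_config(prevalence=0.0)

    def test_duplicate_drug_codes_rejected(self):
        spec = pv.DrugSpec(drug_code="N06AB06", label="a", exposure_prevalence=0.1)
        spec2 = pv.DrugSpec(drug_code="N06AB06", label="b", exposure_prevalence=0.1)
        with pytest.raises(ConfigError):
            pv.SyntheticConfig(n_reports=10, baseline_event_logit=-4.0, drug_specs=[spec, spec2])

    def test_adding_a_drug_does_not_perturb_others(self):
        """Per-component RNG streams: an extra drug leaves existing
        exposure draws and covariates unchanged."""
        cfg3 = null_config(n_reports=2000, n_drugs=3, seed=9)
        cfg4 = null_config(n_reports=2000, n_drugs=4, seed=9)
        v3 = config_vocabulary(cfg3)
        d3 = build_analytic_frame(pv.generate_frames(cfg3), v3).df
        d4 = build_analytic_frame(pv.generate_frames(cfg4), config_vocabulary(cfg4)).df
        for col in ("age_group", "sex", "exp_drug1", "exp_drug2", "exp_drug3"):
            assert (d3[col].to_numpy() == d4[col].to_numpy()).all()


class TestCalibration:
    def test_null_ror_within_monte_carlo_noise(self):
        """All planted log-ORs zero: each drug's empirical log ROR is
        within 3 Woolf SEs of 0."""
        cfg = null_config(n_reports=50_000, seed=7)
        ds = build_analytic_frame(pv.generate_frames(cfg), config_vocabulary(cfg))
        for spec in cfg.drug_specs:
            t = ds.contingency(spec.label)
            ror, lo, hi = pv.compute_ror(t)
            se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
            assert abs(math.log(ror)) < 3 * se

    def test_or_estimator_consistency(self):
        """Planted OR 1.5, no confounding, n = 500,000: the crude ROR lands
        within 3 Woolf SEs of truth."""
        cfg = null_config(
            n_reports=500_000, n_drugs=1, log_or=math.log(1.5), seed=13
        )
        ds = build_analytic_frame(pv.generate_frames(cfg), config_vocabulary(cfg))
        t = ds.contingency("drug1")
        ror, _, _ = pv.compute_ror(t)
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
        assert abs(math.log(ror) - math.log(1.5)) < 3 * se

    def test_marginal_rates_converge(self):
        """With no covariate effects and no confounding the empirical
        exposure prevalence and event rate match the configured values
        (3-sigma binomial bands at n = 1e5)."""
        cfg = null_config(n_reports=100_000, prevalence=0.08, seed=3)
        frames = pv.generate_frames(cfg)
        ds = build_analytic_frame(frames, config_vocabulary(cfg))
        n = cfg.n_reports
        p_event = 1 / (1 + math.exp(-cfg.baseline_event_logit))
        rate = ds.case_mask().mean()
        assert abs(rate - p_event) < 3 * math.sqrt(p_event * (1 - p_event) / n)
        for spec in cfg.drug_specs:
            obs = ds.exposure_mask(spec.label).mean()
            band = 3 * math.sqrt(0.08 * 0.92 / n)
            assert abs(obs - 0.08) < band

    def test_confounding_inflates_crude_ror(self):
        """Positive exposure-confounding with positive covariate effects
        biases the crude ROR above the planted OR (sign test, 20
        replicates)."""
        conf = pv.ConfounderSpec(
            p_antihypertensive=0.3,
            log_or_antihypertensive=1.2,
            log_or_age={"45-64": 0.4, "65-74": 0.6, "75plus": 0.8},
            exposure_confounding_log_or=1.0,
        )
        cfg = null_config(
            n_reports=20_000, n_drugs=1, log_or=math.log(1.5), confounders=conf
        )
        above = 0
        for seed in range(20):
            c = dataclasses.replace(cfg, seed=seed)
            ds = build_analytic_frame(pv.generate_frames(c), config_vocabulary(c))
            ror, _, _ = pv.compute_ror(ds.contingency("drug1"))
            above += ror > 1.5
        assert above >= 15  # one-sided binomial p < 0.025 under fairness


class TestPaperLikeConfig:
    def test_nine_target_drugs(self):
        cfg = pv.make_paper_like_config()
        assert len(cfg.drug_specs) == 9
        labels = {s.label for s in cfg.drug_specs}
        assert {"sertraline", "fluoxetine", "zimeldine", "alaproclate", "etoperidone"} <= labels

    def test_zero_scale_rejected(self):
        with pytest.raises(ConfigError):
            pv.make_paper_like_config(scale=0)

    def test_exposed_case_rate_near_two_percent(self):
        """The default configuration implies ~2.2% case rate among reports
        exposed to at least one target drug."""
        cfg = pv.make_paper_like_config(scale=0.05, seed=21)
        ds = build_analytic_frame(pv.generate_frames(cfg), config_vocabulary(cfg))
        exposed = ds.exposure_mask(CLASS_LABEL)
        rate = ds.case_mask()[exposed].mean()
        assert 0.017 < rate < 0.028

    def test_structure_matches_icsr_contract(self):
        """Generated databases survive the strict object-level validation
        and carry doses, dates and challenge outcomes."""
        cfg = dataclasses.replace(pv.make_paper_like_config(scale=0.001, seed=2))
        reports = pv.generate_database(cfg)
        assert len(reports) == 1000
        assert all(r.reactions for r in reports)
        assert all(r.drugs for r in reports)
        doses = [
            d.daily_dose_mg
            for r in reports
            for d in r.drugs
            if d.daily_dose_mg is not None
        ]
        assert doses and all(v >= 0 for v in doses)
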