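import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.dataset import build_analytic_dataset, build_analytic_frame
from pvsignal.disproportionality import (
    Z_95,
    adjusted_ror,
    compute_ror,
    fit_logistic,
    signal_flag,
)
from pvsignal.pipeline import config_vocabulary
from pvsignal.types import ContingencyTable

from conftest import null_config


def woolf_ci(a, b, c, d):
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = a * d / (b * c)
    return ror, math.exp(math.log(ror) - Z_95 * se), math.exp(math.log(ror) + Z_95 * se)


def expand_table(a, b, c, d):
    """Individual-level outcome/design arrays for a 2x2 table (grouped)."""
    y = np.array([1.0, 0.0, 1.0, 0.0])
    X = np.array([[1.0, 1.0], [1.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
    w = np.array([a, b, c, d], dtype=float)
    return y, X, w


class TestComputeRor:
    def test_no_exposed_case_is_undefined(self):
        assert compute_ror(ContingencyTable(0, 1, 100, 900)) == (None, None, None)
        assert compute_ror(ContingencyTable(0, 0, 100, 900)) == (None, None, None)

    def test_null_table_is_exactly_one(self):
        ror, lo, hi = compute_ror(ContingencyTable(10, 90, 100, 900))
        assert ror == pytest.approx(1.0)
        # CI symmetric around 1 on the log scale
        assert math.log(lo) == pytest.approx(-math.log(hi))

    def test_hand_computed_example(self):
        ror, lo, hi = compute_ror(ContingencyTable(20, 80, 100, 900))
        assert ror == pytest.approx(2.25)
        exp_ror, exp_lo, exp_hi = woolf_ci(20, 80, 100, 900)
        assert (lo, hi) == pytest.approx((exp_lo, exp_hi))
        assert round(lo, 2) == 1.32 and round(hi, 2) == 3.83

    def test_haldane_correction_on_zero_cell(self):
        ror, lo, hi = compute_ror(ContingencyTable(5, 0, 100, 900))
        exp_ror = (5.5 * 900.5) / (0.5 * 100.5)
        assert ror == pytest.approx(exp_ror)
        assert lo < ror < hi

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    @given(
        a=st.integers(1, 500), b=st.integers(1, 500),
        c=st.integers(1, 500), d=st.integers(1, 500),
        k=st.integers(2, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, a, b, c, d, k):
        """Scaling all four cells by k leaves the point estimate unchanged
        and shrinks the CI."""
        r1, lo1, hi1 = compute_ror(ContingencyTable(a, b, c, d))
        r2, lo2, hi2 = compute_ror(ContingencyTable(k * a, k * b, k * c, k * d))
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert (hi2 / lo2) < (hi1 / lo1)


class TestSignalFlag:
    @pytest.mark.parametrize(
        "ror,ci_low,expected",
        [
            (1.45, 1.43, True),
            (1.01, 0.88, False),
            (0.56, 0.28, False),
            (1.20, 1.00, False),  # boundary is strict
            (1.00, 1.20, False),
        ],
    )
    def test_rule(self, ror, ci_low, expected):
        assert signal_flag(ror, ci_low) is expected

    def test_undefined_inputs(self):
        assert signal_flag(None, None) is None
        assert signal_flag(1.4, None) is None


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0] * 30 + [0.0] * 70)
        X = np.ones((100, 1))
        fit = fit_logistic(y, X)
        assert fit.ok
        assert fit.params[0] == pytest.approx(math.log(0.3 / 0.7), abs=1e-9)

    def test_two_by_two_identity(self):
        """Saturated 2x2 logistic: exp(slope) = ad/bc and Wald CI = Woolf CI."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 300, size=4)
            y, X, w = expand_table(a, b, c, d)
            fit = fit_logistic(y, X, weights=w)
            assert fit.ok
            ror, lo, hi = woolf_ci(a, b, c, d)
            assert math.exp(fit.params[1]) == pytest.approx(ror, rel=1e-6)
            assert math.exp(fit.params[1] - Z_95 * fit.bse[1]) == pytest.approx(lo, rel=1e-6)
            assert math.exp(fit.params[1] + Z_95 * fit.bse[1]) == pytest.approx(hi, rel=1e-6)

    def test_matches_statsmodels_glm(self):
        """Independent oracle: coefficients and standard errors agree with
        a GLM-Binomial fit on random multivariable data."""
        import statsmodels.api as sm

        rng = np.random.default_rng(11)
        n = 2000
        X = np.column_stack(
            [np.ones(n), rng.integers(0, 2, n), rng.standard_normal(n), rng.integers(0, 2, n)]
        ).astype(float)
        beta_true = np.array([-1.5, 0.4, 0.3, -0.2])
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert ours.ok
        np.testing.assert_allclose(ours.params, ref.params, rtol=1e-6)
        np.testing.assert_allclose(ours.bse, ref.bse, rtol=1e-5)

    def test_separation_flagged(self):
        """Perfectly separated data (all exposed are cases) must not return
        a quietly diverged estimate."""
        y = np.array([1.0] * 20 + [0.0] * 20)
        X = np.column_stack([np.ones(40), y.copy()])
        fit = fit_logistic(y, X)
        assert not fit.ok


class TestAdjustedRor:
    def test_no_confounding_collapse(self):
        """Covariates independent of exposure and outcome: aROR within 1%
        of the crude ROR at n = 1e5."""
        conf = pv.ConfounderSpec(p_antihypertensive=0.2, p_hypertensive_inducer=0.2)
        cfg = null_config(
            n_reports=100_000, n_drugs=1, log_or=math.log(1.5), confounders=conf, seed=23
        )
        ds = build_analytic_frame(pv.generate_frames(cfg), config_vocabulary(cfg))
        ror, _, _ = pv.compute_ror(ds.contingency("drug1"))
        aror, lo, hi = adjusted_ror(ds, "drug1")
        assert aror == pytest.approx(ror, rel=0.01)

    def test_confounding_recovery(self):
        """Planted OR 1.5 with strong confounding: the crude ROR is biased
        high while the adjusted CI covers the truth."""
        conf = pv.ConfounderSpec(
            p_antihypertensive=0.3,
            log_or_antihypertensive=1.5,
            log_or_age={"45-64": 0.5, "65-74": 0.7, "75plus": 0.9},
            exposure_confounding_log_or=1.2,
        )
        cfg = null_config(
            n_reports=150_000, n_drugs=1, log_or=math.log(1.5), confounders=conf, seed=31
        )
        ds = build_analytic_frame(pv.generate_frames(cfg), config_vocabulary(cfg))
        ror, _, _ = pv.compute_ror(ds.contingency("drug1"))
        aror, lo, hi = adjusted_ror(ds, "drug1")
        assert ror > 1.6  # visibly confounded
        assert lo < 1.5 < hi

    def test_degenerate_covariates_reduce_to_crude(self, vocab):
        """All covariates constant: the adjusted model collapses to the
        exposure-only model, whose OR is the crude ROR."""
        from conftest import make_report

        reports = []
        for i in range(40):
            exposed = i < 20
            case = (i % 4 == 0) if exposed else (i % 8 == 0)
            reports.append(
                make_report(
                    f"R{i}",
                    terms=["Hypertension"] if case else ["Nausea"],
                    drugs=[("N06AB06", "suspect")] if exposed else [("A02BC01", "suspect")],
                    age_group="45-64",
                    sex="female",
                )
            )
        ds = build_analytic_dataset(reports, vocab)
        ror, _, _ = pv.compute_ror(ds.contingency("sertraline"))
        aror, _, _ = adjusted_ror(ds, "sertraline")
        assert aror == pytest.approx(ror, rel=1e-6)

    def test_no_exposed_case_undefined(self, vocab):
        from conftest import make_report

        reports = [
            make_report("R1", terms=["Nausea"], drugs=[("N06AB06", "suspect")]),
            make_report("R2", terms=["Hypertension"], drugs=[("A02BC01", "suspect")]),
        ]
        ds = build_analytic_dataset(reports, vocab)
        assert adjusted_ror(ds, "sertraline") == (None, None, None)


class TestSignalResults:
    def test_rows_alphabetical_with_class_last(self, vocab, ten_report_db):
        ds = build_analytic_dataset(ten_report_db, vocab)
        rows = pv.signal_results(ds, adjusted=False)
        assert [r.drug for r in rows] == ["fluoxetine", "sertraline", "SRI class"]

    def test_signal_invariants(self):
        cfg = null_config(n_reports=20_000, log_or=math.log(2.0), seed=3)
        ds = build_analytic_frame(pv.generate_frames(cfg), config_vocabulary(cfg))
        for r in pv.signal_results(ds, adjusted=True):
            if r.ror is not None:
                assert r.ci_low <= r.ror <= r.ci_high
                assert r.signal == (r.ror > 1 and r.ci_low > 1)
            if r.aror is not None:
                assert r.aci_low <= r.aror <= r.aci_high
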