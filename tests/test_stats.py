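"""Statistical layer against independent oracles (normal equations,
hand-computed ANOVA mean squares, closed-form normal tails, pingouin)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pcltunnel.stats import (
    IccResult,
    RegressionFit,
    compare_groups,
    correlate,
    fit_linear,
    icc,
    icc_category,
    normality_test,
    predict_ttl,
    safety_rate,
    strength_label,
)


class TestNormality:
    def test_null_rejection_rate_near_alpha(self):
        """Lilliefors-corrected KS on truly normal samples rejects at roughly
        the nominal 5% level."""
        rng = np.random.default_rng(7)
        rejections = sum(
            not normality_test(rng.normal(size=150)).is_normal for _ in range(300)
        )
        assert 0.015 <= rejections / 300 <= 0.10

    def test_exponential_sample_rejected(self):
        rng = np.random.default_rng(3)
        res = normality_test(rng.exponential(size=500))
        assert not res.is_normal

    def test_small_or_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_test([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            normality_test([2.0] * 10)


class TestCorrelate:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.normal(size=60)
        up = correlate(x, 2 * x + 1)
        down = correlate(x, -x)
        assert up.r == pytest.approx(1.0)
        assert up.strength == "strong"
        assert down.r == pytest.approx(-1.0)

    def test_non_normal_variable_switches_to_spearman(self, rng):
        x = rng.normal(size=300)
        y = rng.exponential(size=300) ** 3
        assert correlate(x, y).method == "spearman"
        assert correlate(x, 0.5 * x + rng.normal(size=300)).method == "pearson"

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])

    @pytest.mark.parametrize(
        "r,label",
        [
            (0.05, "negligible"),
            (0.1, "weak"),
            (0.29, "weak"),
            (0.3, "moderate"),
            (0.65, "moderate"),
            (0.7, "strong"),
            (1.0, "strong"),
            (-0.65, "moderate"),
        ],
    )
    def test_strength_bands_at_printed_cut_points(self, r, label):
        assert strength_label(r) == label


class TestFitLinear:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_normal_equations_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 10, 10)
        y = rng.normal(size=10)
        fit = fit_linear(x, y)
        # independent oracle: solve X'X b = X'y directly
        X = np.stack([x, np.ones_like(x)], axis=1)
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        resid = y - (slope * x + intercept)
        assert fit.residual_sd == pytest.approx(
            math.sqrt(resid @ resid / (len(x) - 2)), abs=1e-10
        )

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            fit_linear([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(3))
    def test_balanced_design_slope_equals_slope_of_angle_means(self, seed):
        """With one measurement per subject at every angle, the pooled OLS
        slope equals the OLS slope through the per-angle means (exactly)."""
        rng = np.random.default_rng(100 + seed)
        angles = np.array([40.0, 45.0, 50.0, 55.0, 60.0])
        table = 1.0 * angles + 15 + rng.normal(0, 5, size=(31, 5))
        pooled = fit_linear(np.tile(angles, 31), table.ravel())
        via_means = fit_linear(angles, table.mean(axis=0))
        assert pooled.slope == pytest.approx(via_means.slope, abs=1e-10)
        assert pooled.intercept == pytest.approx(via_means.intercept, abs=1e-10)


class TestPredict:
    def test_printed_coefficients_at_50_degrees(self):
        pred = predict_ttl((1.04, 14.96), 50.0)
        assert pred.value == pytest.approx(66.96, abs=1e-12)
        assert not pred.extrapolated

    def test_intercept_at_zero_flags_extrapolation(self):
        pred = predict_ttl((2.0, 7.0), 0.0)
        assert pred.value == pytest.approx(7.0)
        assert pred.extrapolated

    def test_guard_band_edges(self):
        assert not predict_ttl((1, 0), 35.0).extrapolated
        assert not predict_ttl((1, 0), 65.0).extrapolated
        assert predict_ttl((1, 0), 80.0).extrapolated


class TestSafetyRate:
    def _fit(self, residual_sd):
        return RegressionFit(
            slope=1.0, intercept=0.0, r_squared=0.9, residual_sd=residual_sd, n=100
        )

    def test_zero_residuals_are_fully_safe(self):
        x = np.arange(20.0)
        fit = fit_linear(x, 3 * x + 2)
        est = safety_rate(fit, x, 3 * x + 2)
        assert est.safety_rate == 1.0

    def test_empirical_matches_normal_tail_at_sigma_four(self):
        """Residuals ~ N(0, 4 mm): the 8-mm empirical safety rate approaches
        Phi(2) ~ 0.977, and the two estimators agree within MC error."""
        rng = np.random.default_rng(11)
        n = 100_000
        x = rng.uniform(40, 60, n)
        y = 1.0 * x + 15 + rng.normal(0, 4.0, n)
        fit = fit_linear(x, y)
        emp = safety_rate(fit, x, y, 8.0, "empirical")
        par = safety_rate(fit, x, y, 8.0, "normal_model")
        expected = sps.norm.cdf(2.0)
        assert emp.safety_rate == pytest.approx(expected, abs=0.005)
        assert par.safety_rate == pytest.approx(emp.safety_rate, abs=0.005)

    def test_monotone_in_residual_sd_and_safe_distance(self):
        rates_sd = [
            safety_rate(self._fit(s), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 8.0, "normal_model").safety_rate
            for s in (2.0, 4.0, 8.0)
        ]
        assert rates_sd[0] >= rates_sd[1] >= rates_sd[2]
        rates_d = [
            safety_rate(self._fit(4.0), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], d, "normal_model").safety_rate
            for d in (4.0, 8.0, 12.0)
        ]
        assert rates_d[0] <= rates_d[1] <= rates_d[2]

    def test_degenerate_zero_residual_model(self):
        est = safety_rate(self._fit(0.0), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 8.0, "normal_model")
        assert est.safety_rate == 1.0
        assert est.degenerate


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert not res.significant

    def test_five_sd_shift_is_significant(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(5, 1, 50)
        assert compare_groups(a, b).p_value < 1e-3

    def test_matches_pooled_variance_formula(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1.3, 17)
        res = compare_groups(a, b)
        # textbook pooled-variance t statistic
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.statistic == pytest.approx(t, abs=1e-10)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestIcc:
    def test_identical_columns_give_perfect_agreement(self):
        m = np.tile(np.array([50.0, 55.0, 60.0, 62.0, 70.0])[:, None], (1, 2))
        res = icc(m)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.category == "excellent"

    def test_matches_hand_computed_mean_squares(self):
        """Five-subject toy table worked through the two-way ANOVA mean
        squares by hand."""
        m = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 9.0], [2.0, 6.0], [7.0, 8.0]])
        n, k = m.shape
        grand = m.mean()
        msr = k * ((m.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((m.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(m).icc == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        m = rng.normal(60, 8, size=(12, 2))
        m[:, 1] = m[:, 0] + rng.normal(0, 1.5, 12)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": m.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
        # two-way random, absolute agreement, single measure (label varies
        # across pingouin versions)
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(m).icc == pytest.approx(icc2, abs=1e-8)

    @pytest.mark.parametrize(
        "value,category",
        [(0.3, "poor"), (0.5, "moderate"), (0.74, "moderate"), (0.75, "good"),
         (0.90, "good"), (0.924, "excellent")],
    )
    def test_agreement_bands(self, value, category):
        assert icc_category(value) == category

    def test_missing_values_rejected(self):
        m = np.array([[1.0, 2.0], [3.0, np.nan], [5.0, 6.0], [7.0, 8.0], [9.0, 1.0]])
        with pytest.raises(ValueError):
            icc(m)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((3, 2)) + np.arange(3)[:, None])


class TestProperties:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=10, max_size=24))
    def test_icc_bounded_above_by_one(self, flat):
        m = np.asarray(flat[: 2 * (len(flat) // 2)]).reshape(-1, 2)
        if len(m) < 5 or np.ptp(m) == 0:
            return
        assert icc(m).icc <= 1.0 + 1e-12

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.floats(0.1, 10.0),
        st.floats(0.0, 20.0),
        st.floats(0.0, 20.0),
    )
    def test_safety_rate_monotone_in_safe_distance(self, sd, d1, d2):
        fit = RegressionFit(slope=1.0, intercept=0.0, r_squared=0.5,
                            residual_sd=sd, n=50)
        lo, hi = sorted((d1, d2))
        x = np.array([1.0, 2.0, 3.0])
        r_lo = safety_rate(fit, x, x, lo, "normal_model").safety_rate
        r_hi = safety_rate(fit, x, x, hi, "normal_model").safety_rate
        assert 0.0 <= r_lo <= r_hi <= 1.0
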