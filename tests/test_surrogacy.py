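"""Effect measures, Spearman correlation, and the weighted log-log regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from oncosurrogacy.surrogacy import (
    SURROGATE_FIELDS,
    ComparisonRecord,
    SurrogacyModel,
    effect_ratio,
    evaluate_all,
    rr_from_counts,
    spearman_corr,
    wls_loglog_fit,
)

positive = st.floats(1e-3, 1e3, allow_nan=False, allow_infinity=False)


def make_comparisons(x, y, w, surrogate="ratio_rmst_24"):
    """Comparison table with hr_os = 10**y and surrogate = 10**x."""
    return pd.DataFrame(
        {
            "trial_id": [f"T{i}" for i in range(len(x))],
            "experimental_arm_id": "exp",
            "control_arm_id": "ctrl",
            "n_total": w,
            "hr_os": 10.0 ** np.asarray(y),
            surrogate: 10.0 ** np.asarray(x),
        }
    )


class TestEffectRatios:
    def test_identical_arms(self):
        assert effect_ratio(0.5, 0.5) == 1.0

    def test_arithmetic(self):
        assert effect_ratio(6.0, 4.0) == pytest.approx(1.5)

    @given(positive, positive)
    def test_reciprocity(self, a, b):
        assert effect_ratio(a, b) * effect_ratio(b, a) == pytest.approx(1.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError, match="non-positive effect value"):
            effect_ratio(0.0, 1.0)
        with pytest.raises(ValueError, match="non-positive effect value"):
            effect_ratio(1.0, -2.0)

    def test_rr_from_counts(self):
        assert rr_from_counts(30, 50, 20, 50) == pytest.approx(1.5)
        assert rr_from_counts(10, 40, 25, 100) == pytest.approx(1.0)
        assert rr_from_counts(0, 50, 10, 50) == 0.0  # zero numerator is defined

    def test_rr_zero_control_undefined(self):
        with pytest.raises(ValueError, match="undefined relative risk"):
            rr_from_counts(10, 50, 0, 50)
        with pytest.raises(ValueError, match="invalid counts"):
            rr_from_counts(60, 50, 10, 50)


class TestSpearman:
    def test_perfect_inverse_monotone(self):
        r, p = spearman_corr([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_transform(self):
        x = np.array([0.3, 1.2, 2.7, 3.1, 5.0])
        r, _ = spearman_corr(x, np.exp(x))
        assert r == pytest.approx(1.0)

    def test_sign_flips_under_negation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        r1, _ = spearman_corr(x, y)
        r2, _ = spearman_corr(x, -y)
        assert r1 == pytest.approx(-r2)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(2)
        for n in (5, 9, 20):
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            r, p = spearman_corr(x, y)
            ref = stats.spearmanr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_handles_ties_via_midranks(self):
        x = [1.0, 1.0, 2.0, 3.0, 3.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0]
        r, _ = spearman_corr(x, y)
        ref = stats.spearmanr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero rank variance"):
            spearman_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_p_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.1, 2.3, 2.9, 4.5, 5.1]
        r, p_exact = spearman_corr(x, y, method="permutation")
        assert r == pytest.approx(1.0)
        # perfectly concordant ranks: 2 of 5! orderings are as extreme
        assert p_exact == pytest.approx(2 / 120)
        with pytest.raises(ValueError, match="n <= 10"):
            spearman_corr(np.arange(11.0), np.arange(11.0), method="permutation")


class TestWlsLogLog:
    def test_exact_linear_data(self):
        df = make_comparisons([0.0, 1.0, 2.0], [0.0, -0.5, -1.0], [100, 100, 100])
        res = wls_loglog_fit(df, "ratio_rmst_24")
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.slope == pytest.approx(-0.5, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0)
        assert res.regression_p < 1e-10

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=8)
        y = -0.4 * x + rng.normal(scale=0.2, size=8)
        w = rng.integers(50, 500, size=8)
        a = wls_loglog_fit(make_comparisons(x, y, w), "ratio_rmst_24")
        b = wls_loglog_fit(make_comparisons(x, y, 10 * w), "ratio_rmst_24")
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)
        assert a.slope == pytest.approx(b.slope, rel=1e-12)
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-12)
        assert a.regression_p == pytest.approx(b.regression_p, rel=1e-9)

    def test_agrees_with_statsmodels_oracle(self):
        """Closed-form normal equations vs statsmodels WLS on 20 random
        small datasets, to 1e-10."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            w = rng.uniform(10, 1000, size=n)
            res = wls_loglog_fit(make_comparisons(x, y, w), "ratio_rmst_24")
            ref = sm.WLS(y, sm.add_constant(x), weights=w).fit()
            assert res.intercept == pytest.approx(ref.params[0], abs=1e-10)
            assert res.slope == pytest.approx(ref.params[1], abs=1e-10)
            assert res.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
            assert res.se_slope == pytest.approx(ref.bse[1], abs=1e-10)
            assert res.regression_p == pytest.approx(ref.pvalues[1], abs=1e-10)

    def test_r_squared_equals_squared_weighted_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = 0.8 * x + rng.normal(scale=0.3, size=10)
        w = rng.uniform(50, 800, size=10)
        res = wls_loglog_fit(make_comparisons(x, y, w), "ratio_rmst_24")
        sw = w.sum()
        xm, ym = np.sum(w * x) / sw, np.sum(w * y) / sw
        num = np.sum(w * (x - xm) * (y - ym))
        den = np.sqrt(np.sum(w * (x - xm) ** 2) * np.sum(w * (y - ym) ** 2))
        assert res.r_squared == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_log_base_changes_intercept_not_slope(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=7)
        y = -0.6 * x + rng.normal(scale=0.1, size=7)
        df = make_comparisons(x, y, np.full(7, 100))
        b10 = wls_loglog_fit(df, "ratio_rmst_24", log_base=10)
        be = wls_loglog_fit(df, "ratio_rmst_24", log_base=np.e)
        assert b10.slope == pytest.approx(be.slope, rel=1e-10)
        assert b10.r_squared == pytest.approx(be.r_squared, rel=1e-10)
        assert b10.intercept != pytest.approx(be.intercept)

    def test_insufficient_comparisons_rejected(self):
        df = make_comparisons([0.0, 1.0], [0.0, -0.5], [100, 100])
        with pytest.raises(ValueError, match="insufficient comparisons"):
            wls_loglog_fit(df, "ratio_rmst_24")

    def test_non_positive_effect_rejected(self):
        df = make_comparisons([0.0, 1.0, 2.0], [0.0, -0.5, -1.0], [100, 100, 100])
        df.loc[1, "hr_os"] = -0.2
        with pytest.raises(ValueError, match="non-positive effect"):
            wls_loglog_fit(df, "ratio_rmst_24")

    def test_equation_formatting(self):
        df = make_comparisons([0.0, 1.0, 2.0], [0.1, -0.4, -0.9], [100, 100, 100])
        res = wls_loglog_fit(df, "ratio_rmst_24")
        eq = res.equation()
        assert eq.startswith("Log (HRos) = ")
        assert "24-month OS milestone RMST" in eq


class TestComparisonRecord:
    def test_requires_positive_effects(self):
        with pytest.raises(ValueError, match="non-positive effect"):
            ComparisonRecord(
                trial_id="T", experimental_arm_id="e", control_arm_id="c",
                n_total=100, hr_os=-1.0,
            )

    def test_optional_measures_may_be_absent(self):
        rec = ComparisonRecord(
            trial_id="T", experimental_arm_id="e", control_arm_id="c",
            n_total=100, hr_os=0.8,
        )
        assert rec.hr_pfs is None


class TestEvaluateAll:
    def _suite(self, rng, n=10):
        x = rng.uniform(-0.15, 0.1, size=n)  # log10 surrogate effects
        y = -2.0 * x + rng.normal(scale=0.01, size=n)
        df = make_comparisons(x, y, rng.integers(100, 900, size=n))
        for col in SURROGATE_FIELDS:
            if col not in df.columns:
                df[col] = 10.0 ** rng.normal(scale=0.05, size=n)
        return df

    def test_exact_power_law_gives_unit_r_squared(self):
        rng = np.random.default_rng(7)
        df = self._suite(rng)
        df["ratio_rmst_24"] = df["hr_os"] ** (-0.5)  # exact log-linear relation
        results = {r.surrogate_name: r for r in evaluate_all(df)}
        assert results["ratio_rmst_24"].r_squared == pytest.approx(1.0)

    def test_permutation_destroys_one_association_only(self):
        """Shuffling one surrogate's values across comparisons removes its
        association (null mean R2 is ~1/(n-1)) and leaves the others alone."""
        rng = np.random.default_rng(8)
        df = self._suite(rng)
        before = {r.surrogate_name: r for r in evaluate_all(df)}
        assert before["ratio_rmst_24"].r_squared > 0.9
        perm_r2 = []
        shuffled = df.copy()
        for _ in range(20):
            shuffled["ratio_rmst_24"] = rng.permutation(df["ratio_rmst_24"].to_numpy())
            perm_r2.append(wls_loglog_fit(shuffled, "ratio_rmst_24").r_squared)
        assert np.mean(perm_r2) < 0.3
        assert np.mean(perm_r2) < before["ratio_rmst_24"].r_squared / 3
        after = {r.surrogate_name: r for r in evaluate_all(shuffled)}
        for name in SURROGATE_FIELDS:
            if name != "ratio_rmst_24":
                assert after[name].r_squared == pytest.approx(before[name].r_squared)

    def test_complete_case_per_surrogate(self):
        rng = np.random.default_rng(9)
        df = self._suite(rng, n=9)
        df.loc[df.index[:1], "ratio_rmst_24"] = np.nan  # n = 8 at 24 months
        df.loc[df.index[:3], "rr_dcr"] = np.nan  # n = 6 for DCR
        results = {r.surrogate_name: r for r in evaluate_all(df)}
        assert results["ratio_rmst_12"].n_comparisons == 9
        assert results["ratio_rmst_24"].n_comparisons == 8
        assert results["rr_dcr"].n_comparisons == 6

    def test_surrogate_with_too_few_cases_is_skipped(self):
        rng = np.random.default_rng(10)
        df = self._suite(rng, n=4)
        df.loc[df.index[:2], "rr_orr"] = np.nan
        names = [r.surrogate_name for r in evaluate_all(df)]
        assert "rr_orr" not in names
        assert "ratio_rmst_24" in names


class TestModelResultsInterface:
    def test_summary_and_predict(self):
        df = make_comparisons([0.0, 1.0, 2.0, 3.0], [0.0, -0.5, -1.0, -1.5], [100] * 4)
        res = SurrogacyModel.from_comparisons(df, "ratio_rmst_24").fit()
        text = res.summary()
        assert "weighted R2" in text and "Spearman r" in text
        pred = res.predict_log_hr_os([1.0, 10.0])
        assert pred[0] == pytest.approx(res.intercept)
        assert pred[1] == pytest.approx(res.intercept + res.slope)

    def test_params_and_bse_vectors(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=6)
        y = -x + rng.normal(scale=0.2, size=6)
        res = wls_loglog_fit(make_comparisons(x, y, np.full(6, 50)), "ratio_rmst_24")
        assert res.params.shape == (2,)
        assert np.all(res.bse > 0)
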