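"""Estimation kernel: OLS closed forms, nested REML vs. ANOVA oracle,
the harmonic mixed line vs. an independent mixed-model implementation,
likelihood-ratio comparison, mixed R-squared, splines, and Tukey letters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal

from microbuffer.stats import (
    anova_tukey,
    balanced_nested_anova,
    fit_line_ols,
    fit_mixed_line,
    fit_mixed_model,
    fit_nested_intercept_model,
    fit_penalized_spline,
    lrt_compare,
    predict_random,
    r2_mixed,
)
from microbuffer.stats.mixed import _nested_logliks, _sorted_structure


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

class TestLineOls:
    def test_exact_line(self):
        fit = fit_line_ols([0, 1, 2], [1, 2, 3])
        assert fit.intercept == pytest.approx(1.0)
        assert fit.slope == pytest.approx(1.0)
        assert fit.resid_sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 30, 200)
        y = 2.0 + 0.6 * x + rng.normal(0, 1, 200)
        fit = fit_line_ols(x, y)
        # independent route: direct 2x2 normal-equations solve
        A = np.array([[len(x), x.sum()], [x.sum(), (x * x).sum()]])
        ab = np.linalg.solve(A, np.array([y.sum(), (x * y).sum()]))
        assert fit.intercept == pytest.approx(ab[0], abs=1e-10)
        assert fit.slope == pytest.approx(ab[1], abs=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    def test_offset_slope_identity(self, seed):
        # slope of (y - x) on x equals slope of y on x minus one
        rng = np.random.default_rng(seed)
        x = rng.uniform(-10, 30, 50)
        y = rng.normal(0, 5, 50) + 0.5 * x
        full = fit_line_ols(x, y)
        offset = fit_line_ols(x, y - x)
        assert offset.slope == pytest.approx(full.slope - 1.0, abs=1e-10)
        assert offset.intercept == pytest.approx(full.intercept, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_line_ols([2, 2, 2, 2], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="at least 3"):
            fit_line_ols([1, 2], [1, 2])

    def test_nan_pairs_dropped(self):
        fit = fit_line_ols([0, 1, 2, 3, np.nan], [1, 2, 3, np.nan, 5])
        assert fit.n == 3


# ---------------------------------------------------------------------------
# nested intercept-only REML
# ---------------------------------------------------------------------------

def balanced_data(a, b, c, n, sig, seed, mu=5.0):
    rng = np.random.default_rng(seed)
    month = np.repeat(np.arange(a), b * c * n)
    day = np.repeat(np.arange(a * b), c * n)
    hour = np.repeat(np.arange(a * b * c), n)
    y = (mu + np.repeat(rng.normal(0, np.sqrt(sig[0]), a), b * c * n)
         + np.repeat(rng.normal(0, np.sqrt(sig[1]), a * b), c * n)
         + np.repeat(rng.normal(0, np.sqrt(sig[2]), a * b * c), n)
         + rng.normal(0, np.sqrt(sig[3]), a * b * c * n))
    lab = ([f"m{v}" for v in month], [f"d{v}" for v in day],
           [f"h{v}" for v in hour])
    return y, lab


class TestNestedIntercept:
    def test_constant_series(self):
        y = np.full(24, 3.5)
        lab = (["m1"] * 12 + ["m2"] * 12,
               [f"d{i // 4}" for i in range(24)],
               [f"h{i // 2}" for i in range(24)])
        fit = fit_nested_intercept_model(y, *lab)
        assert fit.mu == 3.5
        assert fit.se_mu == 0.0
        assert all(v == 0.0 for v in fit.sigma2.values())

    def test_reml_matches_balanced_anova_oracle(self):
        # true components (month, day, hour, resid) = (4, 1, 0.25, 1)
        y, lab = balanced_data(8, 6, 4, 3, (4.0, 1.0, 0.25, 1.0), seed=0)
        fit = fit_nested_intercept_model(y, *lab)
        oracle = balanced_nested_anova(y, *lab)
        for name in ("month", "day", "hour"):
            assert fit.sigma2[name] == pytest.approx(
                oracle[name], rel=1e-4)
        assert fit.sigma2_resid == pytest.approx(oracle["resid"], rel=1e-4)

    def test_loglik_matches_direct_multivariate_normal(self):
        rng = np.random.default_rng(1)
        y, lab = balanced_data(3, 2, 2, 2, (0.7, 0.4, 0.25, 0.9), seed=1)
        sig = [0.7, 0.4, 0.25]
        codes = [pd.factorize(pd.Series(lv))[0] for lv in lab]
        order, starts = _sorted_structure(codes)
        ll_ml, _, mu, _ = _nested_logliks(y[order], starts, sig, 0.9)
        n = y.size
        cov = 0.9 * np.eye(n)
        for s, lv in zip(sig, codes):
            Z = (lv[:, None] == np.unique(lv)[None, :]).astype(float)
            cov += s * Z @ Z.T
        direct = multivariate_normal(mean=np.full(n, mu), cov=cov).logpdf(y)
        assert ll_ml == pytest.approx(direct, abs=1e-9)

    def test_non_nested_labels_rejected(self):
        y = np.arange(8.0)
        month = ["m1"] * 4 + ["m2"] * 4
        day = ["d1", "d1", "d2", "d2", "d1", "d1", "d3", "d3"]
        with pytest.raises(ValueError, match="not nested"):
            fit_nested_intercept_model(y, month, day)

    def test_two_level_and_single_level_variants(self):
        rng = np.random.default_rng(4)
        month = np.repeat([f"m{i}" for i in range(6)], 20)
        y = rng.normal(0, 1, 120) + np.repeat(rng.normal(0, 2, 6), 20)
        fit = fit_nested_intercept_model(y, month)
        assert fit.level_names == ("month",)
        assert fit.sigma2["month"] > 0
        assert fit.se_mu > 0


# ---------------------------------------------------------------------------
# mixed line with harmonics
# ---------------------------------------------------------------------------

def line_data(seed, n_month=5, n_day=6, n_obs=8, beta=(2.0, 0.6, 0.8, -0.5),
              sd_month=0.5, sd_day=0.7, sd_resid=1.0):
    rng = np.random.default_rng(seed)
    N = n_month * n_day * n_obs
    month = np.repeat([f"m{i}" for i in range(n_month)], n_day * n_obs)
    day = np.repeat([f"d{i}" for i in range(n_month * n_day)], n_obs)
    x = rng.uniform(0, 30, N)
    h = rng.integers(0, 24, N)
    ang = 2 * np.pi * h / 24
    y = (beta[0] + beta[1] * x + beta[2] * np.sin(ang)
         + beta[3] * np.cos(ang)
         + np.repeat(rng.normal(0, sd_month, n_month), n_day * n_obs)
         + np.repeat(rng.normal(0, sd_day, n_month * n_day), n_obs)
         + rng.normal(0, sd_resid, N))
    return y, x, h, month, day


class TestMixedLine:
    def test_zero_random_variance_reduces_to_ols(self):
        y, x, h, month, day = line_data(0, sd_month=0.0, sd_day=0.0)
        fit = fit_mixed_line(y, x, h, month, day)
        ang = 2 * np.pi * h / 24
        X = np.column_stack([np.ones_like(x), x, np.sin(ang), np.cos(ang)])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-6)

    def test_recovers_known_offset_response_line(self):
        # generative line: intercept 5.6, slope -0.51
        y, x, h, month, day = line_data(1, beta=(5.6, -0.51, 0.3, -0.2))
        fit = fit_mixed_line(y, x, h, month, day)
        c = fit.coef()
        se = dict(zip(fit.names, fit.se_beta))
        # the intercept sees only 5 month groups, so give it 3 se
        assert abs(c["intercept"] - 5.6) < 3 * se["intercept"]
        assert abs(c["x"] - (-0.51)) < 2 * se["x"]

    def test_matches_independent_mixed_model_implementation(self):
        y, x, h, month, day = line_data(2, n_month=4, n_day=5, n_obs=6)
        fit = fit_mixed_line(y, x, h, month, day)
        import statsmodels.api as sm
        ang = 2 * np.pi * h / 24
        df = pd.DataFrame(dict(y=y, x=x, s=np.sin(ang), c=np.cos(ang),
                               m=month, d=day))
        with np.errstate(all="ignore"):
            ref = sm.MixedLM.from_formula(
                "y ~ x + s + c", groups="m", re_formula="1",
                vc_formula={"d": "0 + C(d)"}, data=df).fit(reml=True)
        assert np.allclose(fit.beta, ref.fe_params.values, atol=5e-3)

    def test_null_slope_ci_covers_zero_in_most_seeds(self):
        covered = 0
        for seed in range(20):
            y, x, h, month, day = line_data(seed + 100,
                                            beta=(1.0, 0.0, 0.5, 0.2),
                                            n_month=4, n_day=5, n_obs=6)
            fit = fit_mixed_line(y, x, h, month, day)
            b = fit.coef()["x"]
            se = dict(zip(fit.names, fit.se_beta))["x"]
            covered += abs(b) < 1.96 * se
        assert covered >= 18  # ~95% nominal; >=90% demanded

    def test_rank_deficient_design_rejected(self):
        y, x, h, month, day = line_data(3)
        X = np.column_stack([np.ones_like(x), x, x * 2.0])
        with pytest.raises(ValueError, match="rank"):
            fit_mixed_model(y, X, month, day)

    def test_blups_shrink_toward_zero(self):
        y, x, h, month, day = line_data(4, sd_day=1.5)
        fit = fit_mixed_line(y, x, h, month, day)
        pred = predict_random(fit)
        assert pred.shape == y.shape
        # BLUPs absorb most of the day-to-day spread but shrink inwards
        resid = y - fit.beta[0] - fit.beta[1] * x
        day_means = pd.Series(resid).groupby(list(day)).transform("mean")
        assert 0.2 < np.std(pred) < np.std(day_means) + 0.5


class TestLrtAndR2:
    def test_identical_models_give_zero_chi2(self):
        y, x, h, month, day = line_data(5)
        fit = fit_mixed_line(y, x, h, month, day, method="ML")
        chi2, df, p = lrt_compare(fit, fit)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert df == 0 and p == 1.0

    def test_strong_predictor_detected(self):
        y, x, h, month, day = line_data(6, beta=(2.0, -0.5, 0.0, 0.0),
                                        n_month=5, n_day=8, n_obs=25,
                                        sd_resid=0.1)
        full = fit_mixed_line(y, x, h, month, day)
        null = fit_mixed_model(y, np.ones((y.size, 1)), month, day)
        chi2, df, p = lrt_compare(full, null)
        assert df == 3
        assert p < 1e-6

    def test_r2_marginal_equals_conditional_without_random_effects(self):
        y, x, h, month, day = line_data(7, sd_month=0.0, sd_day=0.0)
        fit = fit_mixed_line(y, x, h, month, day)
        r2m, r2c = r2_mixed(fit)
        assert r2c == pytest.approx(r2m, abs=1e-4)
        assert 0 < r2m <= 1

    def test_r2_with_known_variance_shares(self):
        # fixed-effect variance 2, random 1, residual 1
        rng = np.random.default_rng(8)
        n_month, n_day, n_obs = 6, 10, 20
        N = n_month * n_day * n_obs
        month = np.repeat([f"m{i}" for i in range(n_month)], n_day * n_obs)
        day = np.repeat([f"d{i}" for i in range(n_month * n_day)], n_obs)
        x = rng.normal(0, 1, N) * np.sqrt(2)
        y = (x + np.repeat(rng.normal(0, 1, n_month * n_day), n_obs)
             + rng.normal(0, 1, N))
        fit = fit_mixed_model(y, np.column_stack([np.ones(N), x]),
                              month, day, names=("intercept", "x"))
        r2m, r2c = r2_mixed(fit)
        assert r2m == pytest.approx(0.5, abs=0.05)
        assert r2c == pytest.approx(0.75, abs=0.05)


# ---------------------------------------------------------------------------
# penalized spline
# ---------------------------------------------------------------------------

class TestSpline:
    def test_linear_data_collapses_to_line(self):
        rng = np.random.default_rng(9)
        x = np.sort(rng.uniform(0, 30, 150))
        y = 1.5 + 0.4 * x
        fit = fit_penalized_spline(y, x)
        assert fit.edf <= 1.2
        line = fit_line_ols(x, y)
        assert np.max(np.abs(fit.y_grid - line.predict(fit.x_grid))) < 0.05

    def test_quadratic_recovered(self):
        rng = np.random.default_rng(10)
        x = np.sort(rng.uniform(-2, 2, 400))
        y = x**2 + rng.normal(0, 0.05, x.size)
        fit = fit_penalized_spline(y, x)
        rmse = np.sqrt(np.mean((fit.y_grid - fit.x_grid**2) ** 2))
        assert rmse < 0.1
        assert fit.edf > 1.5

    def test_slope_change_yields_extra_degrees_of_freedom(self):
        # offset response flattening below 10 and above 27 degC
        rng = np.random.default_rng(11)
        x = np.sort(rng.uniform(0, 35, 500))
        slope = np.where((x < 10) | (x > 27), -0.1, -0.5)
        y = 3.0 + np.cumsum(slope * np.diff(x, prepend=x[0]))
        y += rng.normal(0, 0.1, x.size)
        fit = fit_penalized_spline(y, x)
        assert fit.edf > 2.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="at least 20"):
            fit_penalized_spline(np.arange(10.0), np.arange(10.0))


# ---------------------------------------------------------------------------
# ANOVA / Tukey letters
# ---------------------------------------------------------------------------

class TestAnovaTukey:
    def test_identical_groups_share_one_letter(self):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, 200)
        labels = np.repeat(list("abcd"), 50)
        comp = anova_tukey(vals, labels)
        assert set(comp.letters.values()) == {"a"}

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(13)
        vals = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        labels = ["g1"] * 50 + ["g2"] * 50
        comp = anova_tukey(vals, labels)
        assert comp.p_value < 1e-10
        assert comp.letters["g1"] != comp.letters["g2"]

    def test_pairwise_p_symmetric_and_label_invariant(self):
        rng = np.random.default_rng(14)
        vals = np.concatenate([rng.normal(0, 1, 40), rng.normal(1, 1, 40),
                               rng.normal(5, 1, 40)])
        labels = ["a"] * 40 + ["b"] * 40 + ["c"] * 40
        comp = anova_tukey(vals, labels)
        # frozenset keys make symmetry structural; relabelling must not
        # change the p-values attached to the same samples
        relabeled = {"a": "z", "b": "y", "c": "x"}
        comp2 = anova_tukey(vals, [relabeled[g] for g in labels])
        for pair, p in comp.tukey_p.items():
            mapped = frozenset(relabeled[g] for g in pair)
            assert comp2.tukey_p[mapped] == pytest.approx(p, abs=1e-12)

    def test_intermediate_group_shares_letters(self):
        rng = np.random.default_rng(15)
        vals = np.concatenate([rng.normal(0, 1, 30), rng.normal(1.2, 1, 30),
                               rng.normal(2.4, 1, 30)])
        labels = ["lo"] * 30 + ["mid"] * 30 + ["hi"] * 30
        comp = anova_tukey(vals, labels)
        if (comp.tukey_p[frozenset(("lo", "mid"))] > 0.05
                and comp.tukey_p[frozenset(("mid", "hi"))] > 0.05
                and comp.tukey_p[frozenset(("lo", "hi"))] < 0.05):
            assert set(comp.letters["mid"]) & set(comp.letters["lo"])
            assert set(comp.letters["mid"]) & set(comp.letters["hi"])
            assert not set(comp.letters["lo"]) & set(comp.letters["hi"])

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])
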