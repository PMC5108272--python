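"""Inferential layer against independent oracles and round-trip simulations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import expit

from litterflame.stats import (
    fit_gaussian_response,
    fit_logistic_threshold,
    linear_fit_by_group,
    pca_correlation,
    pearson_test,
    two_way_anova,
)


# ---------------------------------------------------------------------------
# Pearson

def pearson_oracle(x, y):
    """Direct product-moment formula."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm ** 2) * np.sum(ym ** 2)))


class TestPearson:
    def test_perfect_linearity(self):
        res = pearson_test([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-6)

    def test_df_is_n_minus_2(self):
        rng = np.random.default_rng(0)
        res = pearson_test(rng.normal(size=34), rng.normal(size=34))
        assert res.df == 32

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        res = pearson_test(x, y)
        assert res.r == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        # p from the t reference distribution
        t = res.r * np.sqrt(res.df / (1 - res.r ** 2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.df), rel=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_significance_stars(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=34)
        res = pearson_test(x, x + rng.normal(size=34) * 0.1)
        assert res.stars() == "***"


# ---------------------------------------------------------------------------
# logistic threshold

class TestLogisticThreshold:
    def simulate(self, seed, b=1.5, x50=16.0, n=40, noise_sd=0.05):
        """Proportions from a descending logistic with mean-preserving beta
        noise (sd = noise_sd at the transition, shrinking toward the
        plateaus, matching the quasi-binomial variance structure)."""
        rng = np.random.default_rng(seed)
        x = rng.uniform(2.0, 32.0, n)
        p = np.clip(expit(-b * (x - x50)), 1e-4, 1 - 1e-4)
        m = 0.25 / noise_sd ** 2 - 1  # var at p=0.5 equals noise_sd^2
        return x, rng.beta(m * p, m * (1 - p))

    def test_recovers_midpoint_and_interval(self):
        x, y = self.simulate(seed=10)
        fit = fit_logistic_threshold(x, y)
        assert fit.midpoint == pytest.approx(16.0, abs=1.0)
        lo, hi = fit.transition_interval
        assert lo < fit.midpoint < hi
        assert 12.0 <= lo and hi <= 20.0
        assert fit.p_slope < 0.001
        assert not fit.separated

    def test_matches_glm_crosscheck(self):
        """Independent route: statsmodels binomial GLM on the same data."""
        import statsmodels.api as sm

        x, y = self.simulate(seed=11)
        fit = fit_logistic_threshold(x, y)
        X = sm.add_constant(x)
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        # our parametrisation: eta = -b*(x - x50) = (b*x50) + (-b)*x
        assert -glm.params[1] == pytest.approx(fit.slope, rel=1e-3)
        assert glm.params[0] / fit.slope == pytest.approx(fit.midpoint, rel=1e-3)

    def test_all_high_responses_flag_separation(self):
        x = np.linspace(5, 30, 12)
        fit = fit_logistic_threshold(x, np.ones_like(x))
        assert fit.separated

    def test_binary_separation_flagged(self):
        x = np.linspace(5, 30, 12)
        y = (x < 16).astype(float)
        fit = fit_logistic_threshold(x, y)
        assert fit.separated
        assert fit.midpoint == pytest.approx(16.0, abs=2.0)

    def test_reorder_invariance(self):
        x, y = self.simulate(seed=12)
        fit1 = fit_logistic_threshold(x, y)
        order = np.random.default_rng(0).permutation(len(x))
        fit2 = fit_logistic_threshold(x[order], y[order])
        assert fit2.midpoint == pytest.approx(fit1.midpoint, rel=1e-6)
        assert fit2.slope == pytest.approx(fit1.slope, rel=1e-6)

    def test_affine_rescale_backtransform(self):
        """x -> a*x + c maps slope -> slope/a and midpoint -> a*midpoint + c."""
        x, y = self.simulate(seed=13)
        fit1 = fit_logistic_threshold(x, y)
        a, c = 2.5, 7.0
        fit2 = fit_logistic_threshold(a * x + c, y)
        assert fit2.slope == pytest.approx(fit1.slope / a, rel=1e-4)
        assert fit2.midpoint == pytest.approx(a * fit1.midpoint + c, rel=1e-4)


# ---------------------------------------------------------------------------
# Gaussian response

class TestGaussianResponse:
    def test_noiseless_roundtrip(self):
        x = np.linspace(0, 30, 40)
        y = 500 * np.exp(-((x - 8.0) ** 2) / (2 * 4.0 ** 2)) + 20.0
        fit = fit_gaussian_response(x, y)
        assert fit.amplitude == pytest.approx(500.0, abs=1e-5)
        assert fit.mean == pytest.approx(8.0, abs=1e-6)
        assert fit.sd == pytest.approx(4.0, abs=1e-6)
        assert fit.baseline == pytest.approx(20.0, abs=1e-5)
        assert fit.rss < 1e-10

    def test_constant_response_rejected(self):
        x = np.linspace(0, 30, 10)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_gaussian_response(x, np.full_like(x, 300.0))

    def test_recovery_under_multiplicative_noise(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 30, 60))
        y = 500 * np.exp(-((x - 8.0) ** 2) / (2 * 4.0 ** 2)) + 20.0
        y = y * (1 + rng.normal(0, 0.02, len(x)))
        fit = fit_gaussian_response(x, y)
        assert fit.amplitude == pytest.approx(500.0, rel=0.05)
        assert fit.mean == pytest.approx(8.0, rel=0.05)
        assert fit.sd == pytest.approx(4.0, rel=0.05)


# ---------------------------------------------------------------------------
# two-way ANOVA

def balanced_anova_oracle(df):
    """Classical balanced two-way main-effect SS decomposition by hand."""
    grand = df.aes.mean()
    n = len(df)
    ss = {}
    for factor in ("weighting", "clade_group"):
        ss[factor] = sum(
            len(sub) * (sub.aes.mean() - grand) ** 2 for _, sub in df.groupby(factor))
    fitted = (
        df.groupby("weighting").aes.transform("mean")
        + df.groupby("clade_group").aes.transform("mean") - grand
    )
    ss["resid"] = float(np.sum((df.aes - fitted) ** 2))
    return ss


class TestTwoWayAnova:
    def balanced_frame(self, means, sd, seed=0, reps=6):
        rng = np.random.default_rng(seed)
        rows = []
        for (w, g), mu in means.items():
            for _ in range(reps):
                rows.append({"aes": mu + rng.normal(0, sd) if sd else mu,
                             "weighting": w, "clade_group": g})
        return pd.DataFrame(rows)

    def test_null_case_small_F(self):
        df = self.balanced_frame({("v", "w"): 10, ("v", "o"): 10,
                                  ("m", "w"): 10, ("m", "o"): 10}, sd=1.0, seed=1)
        tab = two_way_anova(df.aes, df.weighting, df.clade_group)
        assert tab["weighting"].F < 5 and tab["clade_group"].F < 5
        assert tab["weighting"].p > 0.01

    def test_hand_oracle_on_noisy_balanced_design(self):
        df = self.balanced_frame({("v", "w"): 10, ("v", "o"): 30,
                                  ("m", "w"): 12, ("m", "o"): 28}, sd=2.0, seed=2)
        tab = two_way_anova(df.aes, df.weighting, df.clade_group)
        oracle = balanced_anova_oracle(df)
        assert tab["weighting"].ss == pytest.approx(oracle["weighting"], rel=1e-9)
        assert tab["clade_group"].ss == pytest.approx(oracle["clade_group"], rel=1e-9)
        assert tab.residual_ss == pytest.approx(oracle["resid"], rel=1e-9)

    def test_zero_within_cell_variance_flags_infinite_F(self):
        df = self.balanced_frame({("v", "w"): 10, ("v", "o"): 30,
                                  ("m", "w"): 10, ("m", "o"): 30}, sd=0.0)
        tab = two_way_anova(df.aes, df.weighting, df.clade_group)
        assert np.isinf(tab["clade_group"].F) and tab["clade_group"].p == 0.0
        assert tab["weighting"].F == 0.0 and tab["weighting"].p == 1.0

    def test_empty_cell_rejected(self):
        df = self.balanced_frame({("v", "w"): 10, ("v", "o"): 30,
                                  ("m", "w"): 10, ("m", "o"): 30}, sd=1.0)
        df = df[~((df.weighting == "m") & (df.clade_group == "o"))]
        with pytest.raises(ValueError, match="2 levels|empty cell"):
            two_way_anova(df.aes, df.weighting, df.clade_group)


# ---------------------------------------------------------------------------
# PCA

class TestPcaCorrelation:
    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=50)
        df = pd.DataFrame({"u": a, "v": 3 * a + 1})
        res = pca_correlation(df)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_variance_shares_match_eigen_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 4)) @ rng.normal(size=(4, 4)),
                          columns=list("abcd"))
        res = pca_correlation(df)
        # brute-force oracle: explicit correlation matrix -> eigenvalues/trace
        z = (df - df.mean()) / df.std(ddof=1)
        corr = (z.T @ z).to_numpy() / (len(df) - 1)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        assert res.variance_explained == pytest.approx(100 * ev / ev.sum(), rel=1e-10)
        assert res.variance_explained.sum() == pytest.approx(100.0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(25, 4)) @ rng.normal(size=(4, 4)),
                          columns=list("abcd"))
        res1 = pca_correlation(df)
        res2 = pca_correlation(df[["c", "a", "d", "b"]])
        assert res2.variance_explained == pytest.approx(res1.variance_explained, rel=1e-9)

    def test_axes_orthonormal(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        res = pca_correlation(df)
        gram = res.loadings.to_numpy().T @ res.loadings.to_numpy()
        assert np.allclose(gram, np.eye(5), atol=1e-10)

    def test_log_column_transform_and_constant_rejection(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"size": 10 ** rng.normal(size=30), "x": rng.normal(size=30)})
        res = pca_correlation(df, log_columns=["size"])
        assert res.variance_explained.shape == (2,)
        df["x"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            pca_correlation(df)


# ---------------------------------------------------------------------------
# per-group OLS

class TestLinearFitByGroup:
    def test_exact_line(self):
        x = np.arange(10.0)
        fits = linear_fit_by_group(x, 2 * x + 1, ["needle"] * 10)
        f = fits["needle"]
        assert f.slope == pytest.approx(2.0)
        assert f.r == pytest.approx(1.0)
        assert f.significant

    def test_small_group_skipped(self):
        with pytest.warns(UserWarning, match="skipped"):
            fits = linear_fit_by_group([1, 2, 1, 2, 3, 4], [1, 2, 2, 4, 6, 8],
                                       ["tiny", "tiny", "big", "big", "big", "big"])
        assert "tiny" not in fits and "big" in fits

    def test_negative_slope_sign_and_permutation_p(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, 20)
        y = -3 * x + rng.normal(0, 0.5, 20)
        fits = linear_fit_by_group(x, y, ["branch"] * 20)
        f = fits["branch"]
        assert f.slope < 0
        # permutation oracle for the two-sided p-value
        robs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        n_perm = 2000
        for _ in range(n_perm):
            count += abs(np.corrcoef(x, rng.permutation(y))[0, 1]) >= robs
        p_perm = (count + 1) / (n_perm + 1)
        assert f.p == pytest.approx(p_perm, abs=max(0.01, 3 * np.sqrt(p_perm / n_perm)))
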