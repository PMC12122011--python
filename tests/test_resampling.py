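"""Residual-row resampling: algebraic identities, determinism, null calibration."""

import numpy as np
import pytest
from scipy import stats

from excesshits import (
    Dataset,
    centered_statistics,
    empirical_cdf,
    fit_ols_many,
    resample_rows,
    run_resampling,
)
from excesshits.resampling import _draw_indices


def _null_dataset(N=200, W=8, seed=0, rho=0.0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(N), rng.standard_normal(N)])
    if rho:
        shared = rng.standard_normal((N, 1))
        Y = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal((N, W))
    else:
        Y = rng.standard_normal((N, W))
    return Dataset(X=X, Y=Y)


class TestResampleRows:
    def test_identity_indices_recover_y(self, random_dataset):
        data = random_dataset(seed=1)
        fit = fit_ols_many(data)
        Yj = resample_rows(fit, data, rng=None, indices=np.arange(data.n_obs))
        np.testing.assert_allclose(Yj, data.Y, atol=1e-12)

    def test_zero_residuals_degenerate(self):
        # exact linear outcome: every resample is the fitted surface
        N = 10
        x = np.linspace(-1, 1, N)
        data = Dataset(X=np.column_stack([np.ones(N), x]), Y=(2 * x + 1)[:, None])
        fit = fit_ols_many(data)
        rng = np.random.default_rng(0)
        for _ in range(5):
            np.testing.assert_allclose(resample_rows(fit, data, rng), fit.fitted, atol=1e-10)

    def test_row_coupling_preserved(self, random_dataset):
        # identical residual columns stay identical: whole rows are drawn
        data = random_dataset(W=1, seed=2)
        dup = Dataset(X=data.X, Y=np.column_stack([data.Y, data.Y]))
        fit = fit_ols_many(dup)
        Yj = resample_rows(fit, dup, np.random.default_rng(3))
        resid_j = Yj - fit.fitted
        np.testing.assert_allclose(resid_j[:, 0], resid_j[:, 1], atol=1e-12)

    def test_design_matrix_never_touched(self, random_dataset):
        data = random_dataset(seed=4)
        X_before = data.X.copy()
        fit = fit_ols_many(data)
        run_resampling(data, B=20, seed=0, fit=fit)
        np.testing.assert_array_equal(data.X, X_before)


class TestCenteredStatistics:
    def test_identity_resample_gives_zero(self, random_dataset):
        data = random_dataset(seed=5)
        fit = fit_ols_many(data)
        np.testing.assert_allclose(centered_statistics(fit, fit), 0.0, atol=1e-12)

    def test_matching_beta_gives_zero_statistic(self, random_dataset):
        data = random_dataset(seed=6, W=2)
        fit = fit_ols_many(data)
        other = fit_ols_many(Dataset(X=data.X, Y=fit.fitted + 0.5 * fit.residuals))
        # same projector => same beta; statistic must be exactly 0
        np.testing.assert_allclose(other.beta, fit.beta, atol=1e-10)
        np.testing.assert_allclose(centered_statistics(fit, other), 0.0, atol=1e-6)


class TestRunResampling:
    def test_deterministic_given_seed(self):
        data = _null_dataset(seed=7)
        d1 = run_resampling(data, B=50, seed=42)
        d2 = run_resampling(data, B=50, seed=42)
        np.testing.assert_array_equal(d1.Tmat, d2.Tmat)
        np.testing.assert_array_equal(d1.counts, d2.counts)

    def test_chunked_projector_path_equals_naive_refit(self):
        # the vectorized engine is an algebraic identity with literally
        # resampling rows and refitting each time
        data = _null_dataset(N=60, W=3, seed=8)
        fit = fit_ols_many(data)
        B = 12
        idx = _draw_indices(np.random.default_rng(9), B, data.n_obs)
        draws = run_resampling(data, B=B, indices=idx, fit=fit, chunk=5)
        for j in range(B):
            Yj = resample_rows(fit, data, rng=None, indices=idx[j])
            fit_j = fit_ols_many(Dataset(X=data.X, Y=Yj))
            Tj = centered_statistics(fit, fit_j)
            np.testing.assert_allclose(draws.Tmat[j], Tj, atol=1e-8)

    def test_variants_identical_for_same_draws(self):
        # for OLS, centered and residual-only statistics coincide in |T|
        data = _null_dataset(N=80, W=4, seed=10)
        idx = _draw_indices(np.random.default_rng(11), 30, 80)
        c = run_resampling(data, B=30, indices=idx, variant="centered")
        r = run_resampling(data, B=30, indices=idx, variant="residual-only")
        np.testing.assert_allclose(np.abs(c.Tmat), np.abs(r.Tmat), atol=1e-8)
        np.testing.assert_array_equal(c.counts, r.counts)

    def test_negated_residual_convention_flips_sign_only(self):
        data = _null_dataset(N=80, W=4, seed=12)
        idx = _draw_indices(np.random.default_rng(13), 25, 80)
        plain = run_resampling(data, B=25, indices=idx)
        neg = run_resampling(data, B=25, indices=idx, negate_residuals=True)
        np.testing.assert_allclose(neg.Tmat, -plain.Tmat, atol=1e-10)
        np.testing.assert_array_equal(neg.counts, plain.counts)

    def test_normal_reference_option(self):
        data = _null_dataset(N=50, W=3, seed=14)
        idx = _draw_indices(np.random.default_rng(15), 20, 50)
        t_ref = run_resampling(data, B=20, indices=idx, reference="t")
        n_ref = run_resampling(data, B=20, indices=idx, reference="normal")
        expect = 2 * stats.norm.sf(np.abs(t_ref.Tmat))
        np.testing.assert_allclose(n_ref.Pmat, expect, atol=1e-12)

    def test_mean_counts_near_w_alpha_independent(self):
        # W = 40 independent outcomes at alpha = .05: E[theta(j)] ~ 2
        data = _null_dataset(N=300, W=40, seed=16)
        draws = run_resampling(data, alpha=0.05, B=2000, seed=17)
        se = draws.counts.std(ddof=1) / np.sqrt(draws.B)
        assert abs(draws.counts.mean() - 2.0) < 3 * se + 0.1

    def test_per_test_rejection_rate_near_alpha_under_alternative(self):
        # Assumption-1 behaviour: resample rejection rate stays ~ alpha even
        # when the data carry real effects
        rng = np.random.default_rng(18)
        N, W = 150, 10
        X = np.column_stack([np.ones(N), rng.standard_normal(N)])
        Y = 0.4 * X[:, [1]] + rng.standard_normal((N, W))
        data = Dataset(X=X, Y=Y)
        alpha, B = 0.05, 2000
        draws = run_resampling(data, alpha=alpha, B=B, seed=19)
        rate = (draws.Pmat < alpha).mean()
        tol = 3 * np.sqrt(alpha * (1 - alpha) / B)
        assert abs(rate - alpha) < tol

    def test_counts_match_binomial_under_independence(self):
        # goodness of fit of resampled counts to Binomial(W, alpha)
        data = _null_dataset(N=1000, W=20, seed=20)
        alpha, B = 0.05, 5000
        draws = run_resampling(data, alpha=alpha, B=B, seed=21)
        dist = stats.binom(20, alpha)
        support = np.arange(21)
        expected = dist.pmf(support) * B
        observed = np.bincount(draws.counts, minlength=21).astype(float)
        # pool the sparse right tail so every bin has expected count >= 5
        cut = np.searchsorted(np.cumsum(expected[::-1]), 5)
        k = 21 - cut - 1
        obs = np.append(observed[:k], observed[k:].sum())
        exp = np.append(expected[:k], expected[k:].sum())
        stat = ((obs - exp) ** 2 / exp).sum()
        pval = stats.chi2.sf(stat, len(obs) - 1)
        assert pval > 0.01

    def test_b_must_be_positive(self):
        with pytest.raises(ValueError):
            run_resampling(_null_dataset(), B=0)


class TestEmpiricalCdf:
    def test_direct_examples(self):
        counts = np.array([0, 1, 2, 3])
        assert empirical_cdf(counts, 1) == 0.5
        assert empirical_cdf(counts, 3) == 1.0
        assert empirical_cdf(np.zeros(10, dtype=int), 0) == 1.0

    def test_monotone_and_reaches_one(self):
        rng = np.random.default_rng(22)
        counts = rng.integers(0, 8, size=200)
        vals = [empirical_cdf(counts, r) for r in range(9)]
        assert vals == sorted(vals)
        assert vals[-1] == 1.0

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf(np.array([0, 1]), -1)
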