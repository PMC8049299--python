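"""Solver-level tests: prox exactness, closed forms, df counting, CV."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize

from cpgfuse.fused import (FeatureChainGraph, count_df, find_blocks,
                           fit_fused_lasso, fused_objective, lambda2_max,
                           nested_cv, prox_chain_fused, tv1d_denoise)


def prox_objective(b, z, l1, l2):
    return (0.5 * np.sum((b - z) ** 2) + l1 * np.sum(np.abs(b))
            + l2 * np.sum(np.abs(np.diff(b))))


def numeric_prox(z, l1, l2):
    """Independent numeric minimizer of the prox objective."""
    res = optimize.minimize(prox_objective, np.zeros_like(z),
                            args=(z, l1, l2), method="Nelder-Mead",
                            options=dict(xatol=1e-10, fatol=1e-12,
                                         maxiter=20000, maxfev=20000))
    return res.x


class TestProx:
    def test_zero_penalties_identity(self, rng):
        z = rng.normal(size=7)
        np.testing.assert_allclose(prox_chain_fused(z, 0.0, 0.0), z)

    def test_matches_numeric_oracle(self):
        z = np.array([1.0, 1.0])
        out = prox_chain_fused(z, 0.5, 7.0)
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)
        oracle = numeric_prox(z, 0.5, 7.0)
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_large_lambda1_gives_zero(self, rng):
        z = rng.normal(size=6) * 3
        tv_out = tv1d_denoise(z, 0.8)
        l1 = np.max(np.abs(tv_out)) + 1e-9
        np.testing.assert_array_equal(prox_chain_fused(z, l1, 0.8),
                                      np.zeros(6))

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            prox_chain_fused(np.ones(3), -1.0, 0.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=12),
           st.floats(0, 3), st.floats(0, 3))
    def test_prox_never_beats_numeric_candidates(self, zs, l1, l2):
        """The prox output's objective is a global minimum: it never exceeds
        the objective at the input, at zero, or at the oracle's point."""
        z = np.array(zs)
        out = prox_chain_fused(z, l1, l2)
        f_out = prox_objective(out, z, l1, l2)
        assert f_out <= prox_objective(z, z, l1, l2) + 1e-9
        assert f_out <= prox_objective(np.zeros_like(z), z, l1, l2) + 1e-9


class TestClosedForms:
    def test_kkt_bound_zero_solution(self, rng):
        X = rng.uniform(0, 1, (40, 8))
        y = rng.normal(size=40)
        g = FeatureChainGraph(2, 4)
        l1 = 2.0 * np.max(np.abs((X - X.mean(0)).T @ (y - y.mean())))
        fit = fit_fused_lasso(X, y, g, l1, 0.0, tol=1e-12, max_iter=50000)
        np.testing.assert_allclose(fit.beta, 0.0, atol=1e-8)
        assert fit.beta0 == pytest.approx(y.mean(), abs=1e-10)

    def test_orthonormal_soft_threshold(self, rng):
        n, p = 50, 6
        A = rng.normal(size=(n, p + 1))
        A[:, 0] = 1.0
        Q, _ = np.linalg.qr(A)
        X = Q[:, 1:]  # orthonormal, orthogonal to the constant
        y = rng.normal(size=n)
        g = FeatureChainGraph(p, 1)
        l1 = 0.7
        fit = fit_fused_lasso(X, y, g, l1, 0.0, tol=1e-14, max_iter=100000)
        z = X.T @ (y - y.mean())
        expected = np.sign(z) * np.maximum(np.abs(z) - l1 / 2.0, 0.0)
        np.testing.assert_allclose(fit.beta, expected, atol=1e-7)

    def test_fusion_limit_collapses_to_ols_on_means(self, rng):
        n, m, k = 60, 3, 5
        g = FeatureChainGraph(m, k)
        X = rng.uniform(0, 1, (n, m * k))
        y = rng.normal(size=n)
        fit = fit_fused_lasso(X, y, g, 0.0, 1e6, tol=1e-14, max_iter=200000)
        B = fit.beta.reshape(m, k)
        assert np.max(B.max(1) - B.min(1)) < 1e-6
        M = np.column_stack([X[:, t * k:(t + 1) * k].mean(1) for t in range(m)])
        A = np.column_stack([np.ones(n), M])
        coef = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(B.mean(axis=1), coef[1:] / k, atol=1e-6)


class TestDf:
    def test_worked_ten_vector(self):
        g = FeatureChainGraph(1, 10)
        beta = np.array([0, 0, .4, .4, .4, -.2, 0, .7, .7, 0])
        assert count_df(beta, g) == 3

    def test_zero_vector(self):
        assert count_df(np.zeros(6), FeatureChainGraph(2, 3)) == 0

    def test_k1_reduces_to_lasso_df(self, rng):
        beta = np.array([0.0, 1.2, 0.0, -0.3, 0.5])
        assert count_df(beta, FeatureChainGraph(5, 1)) == 3

    def test_blocks_structure(self):
        g = FeatureChainGraph(1, 4)
        blocks = find_blocks(np.array([1.0, 1.0, 2.0, 2.0]), g)
        assert blocks == [[(0, 2, 1.0), (2, 4, 2.0)]]


class TestSolverProperties:
    def test_rss_monotone_in_lambda1(self, rng):
        X = rng.uniform(0, 1, (50, 8))
        y = rng.normal(size=50)
        g = FeatureChainGraph(2, 4)
        rss = [fit_fused_lasso(X, y, g, l1, 0.3, tol=1e-11,
                               max_iter=50000).rss
               for l1 in [4.0, 2.0, 1.0, 0.5, 0.0]]
        assert all(rss[i + 1] <= rss[i] + 1e-8 for i in range(len(rss) - 1))

    def test_fusion_limit_range_shrinks(self, rng):
        X = rng.uniform(0, 1, (40, 6))
        y = rng.normal(size=40)
        g = FeatureChainGraph(2, 3)
        ranges = []
        for l2 in [0.1, 10.0, 1000.0]:
            B = fit_fused_lasso(X, y, g, 0.0, l2, tol=1e-12,
                                max_iter=100000).beta.reshape(2, 3)
            ranges.append(np.max(B.max(1) - B.min(1)))
        assert ranges[2] <= ranges[1] <= ranges[0] + 1e-10
        assert ranges[2] < 1e-6

    def test_objective_beats_zero_vector(self, rng):
        X = rng.uniform(0, 1, (30, 6))
        y = rng.normal(size=30)
        g = FeatureChainGraph(3, 2)
        fit = fit_fused_lasso(X, y, g, 0.4, 0.4, tol=1e-11)
        f_fit = fused_objective(X, y, fit.beta0, fit.beta, g, 0.4, 0.4)
        f_zero = fused_objective(X, y, y.mean(), np.zeros(6), g, 0.4, 0.4)
        assert f_fit <= f_zero + 1e-8

    def test_non_finite_rejected(self):
        g = FeatureChainGraph(1, 2)
        with pytest.raises(ValueError):
            fit_fused_lasso(np.array([[np.nan, 0.0]]), np.array([1.0]),
                            g, 0.0, 0.0)

    def test_lambda2_max_fuses_all_chains(self, rng):
        X = rng.uniform(0, 1, (40, 8))
        y = rng.normal(size=40)
        g = FeatureChainGraph(2, 4)
        l2 = lambda2_max(X, y, g)
        B = fit_fused_lasso(X, y, g, 0.0, l2, tol=1e-12,
                            max_iter=100000).beta.reshape(2, 4)
        scale = max(1e-12, np.max(np.abs(B)))
        assert np.max(B.max(1) - B.min(1)) <= 1e-5 * scale


class TestNestedCV:
    def test_deterministic_under_seed(self, rng):
        X = rng.uniform(0, 1, (80, 6))
        beta = np.array([1.0, 1.0, 0.0, 0.0, -1.0, -1.0])
        y = X @ beta + rng.normal(0, 0.3, 80)
        g = FeatureChainGraph(3, 2)
        kwargs = dict(gamma_grid=(0.0, 0.1, 1.0), n_lambda2=4, seed=42)
        rep1, fit1 = nested_cv(X, y, g, **kwargs)
        rep2, fit2 = nested_cv(X, y, g, **kwargs)
        assert [vars(f) for f in rep1.folds] == [vars(f) for f in rep2.folds]
        np.testing.assert_array_equal(fit1.beta, fit2.beta)

    def test_noiseless_signal_near_perfect(self, rng):
        X = rng.uniform(0, 1, (120, 6))
        beta = np.array([2.0, 2.0, 0.0, 0.0, -1.5, -1.5])
        y = X @ beta
        g = FeatureChainGraph(3, 2)
        rep, _ = nested_cv(X, y, g, gamma_grid=(0.0, 0.01, 0.1),
                           n_lambda2=6, seed=1)
        assert np.all(rep.pearson >= 0.99)

    def test_too_few_genes_rejected(self, rng):
        X = rng.uniform(0, 1, (20, 4))
        y = rng.normal(size=20)
        with pytest.raises(ValueError):
            nested_cv(X, y, FeatureChainGraph(2, 2))
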