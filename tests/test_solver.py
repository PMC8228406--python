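"""Unit and property tests for the alternating sparse + low-rank solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slrr
from slrr.solver import (
    FitConfig,
    fit,
    lasso_column,
    lasso_kkt_gap,
    numerical_rank,
    objective,
    svt_prox,
)


class TestObjective:
    def test_all_zero_inputs_give_zero(self):
        Y = np.zeros((3, 2))
        assert objective(Y, np.zeros((3, 4)), np.zeros((4, 2)), np.zeros((3, 2)), 1, 1) == 0.0

    def test_residual_only_term(self, rng):
        Y = rng.standard_normal((5, 3))
        val = objective(Y, np.zeros((5, 2)), np.zeros((2, 3)), np.zeros((5, 3)), 2.0, 3.0)
        assert val == pytest.approx(0.5 * np.sum(Y**2))

    def test_nuclear_norm_of_identity_counts_both_singular_values(self):
        # Y = I2, L = I2 cancel; sum of singular values of I2 is 2
        Y = np.eye(2)
        val = objective(Y, np.zeros((2, 1)), np.zeros((1, 2)), np.eye(2), 1.0, 1.0)
        assert val == pytest.approx(2.0)
        # independent SVD oracle for the nuclear norm
        assert np.linalg.svd(np.eye(2), compute_uv=False).sum() == pytest.approx(2.0)

    def test_dimension_mismatch_names_axis(self):
        with pytest.raises(ValueError, match="sample axis"):
            objective(np.zeros((3, 2)), np.zeros((4, 2)), np.zeros((2, 2)), np.zeros((3, 2)), 1, 1)
        with pytest.raises(ValueError, match="site axis"):
            objective(np.zeros((3, 2)), np.zeros((3, 5)), np.zeros((2, 2)), np.zeros((3, 2)), 1, 1)

    def test_missing_values_direct_to_preprocess(self):
        Y = np.full((2, 2), np.nan)
        with pytest.raises(ValueError, match="preprocess"):
            objective(Y, np.zeros((2, 1)), np.zeros((1, 2)), np.zeros((2, 2)), 1, 1)


class TestSvtProx:
    def test_zero_threshold_is_identity(self, rng):
        M = rng.standard_normal((6, 4))
        L = svt_prox(M, 0.0)
        assert np.linalg.norm(L.values - M) < 1e-10

    def test_full_shrinkage_gives_zero_matrix(self, rng):
        M = rng.standard_normal((5, 3))
        lam = np.linalg.svd(M, compute_uv=False)[0]
        L = svt_prox(M, lam)
        assert np.allclose(L.values, 0.0)
        assert L.numerical_rank == 0

    def test_diagonal_matrix_shrinks_entrywise(self):
        L = svt_prox(np.diag([3.0, 1.0]), 2.0)
        assert np.allclose(L.values, np.diag([1.0, 0.0]))
        assert L.numerical_rank == 1
        assert L.singular_values == pytest.approx([1.0])

    def test_prox_minimizes_its_objective(self, rng):
        # oracle: direct objective evaluation on random perturbed candidates
        M = rng.standard_normal((6, 4))
        lam = 1.0

        def prox_obj(L):
            return 0.5 * np.sum((M - L) ** 2) + lam * np.linalg.svd(L, compute_uv=False).sum()

        best = prox_obj(svt_prox(M, lam).values)
        assert best <= prox_obj(M) + 1e-12
        for _ in range(200):
            cand = svt_prox(M, lam).values + 0.3 * rng.standard_normal((6, 4))
            assert best <= prox_obj(cand) + 1e-12

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_rank_nonincreasing_in_lambda(self, seed):
        M = np.random.default_rng(seed).standard_normal((6, 5))
        lams = np.linspace(0, np.linalg.svd(M, compute_uv=False)[0] * 1.1, 8)
        ranks = [svt_prox(M, lam).numerical_rank for lam in lams]
        assert all(a >= b for a, b in zip(ranks, ranks[1:]))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            svt_prox(np.array([[np.inf, 0.0], [0.0, 1.0]]), 1.0)


class TestLassoColumn:
    def test_unpenalized_orthonormal_equals_projection(self, rng):
        X, _ = np.linalg.qr(rng.standard_normal((20, 5)))
        y = rng.standard_normal(20)
        b = lasso_column(y, X, 0.0, cd_tol=1e-12)
        assert np.allclose(b, X.T @ y, atol=1e-10)

    def test_large_penalty_kkt_null_condition(self, rng):
        X = rng.standard_normal((15, 4))
        y = rng.standard_normal(15)
        rho = np.abs(X.T @ y).max()
        assert np.all(lasso_column(y, X, rho) == 0.0)

    def test_univariate_soft_threshold_closed_form(self, rng):
        x = rng.standard_normal(30)
        x /= np.linalg.norm(x)
        y = rng.standard_normal(30)
        for rho in (0.1, 0.5, 2.0):
            b = lasso_column(y, x[:, None], rho, cd_tol=1e-14)[0]
            xty = x @ y
            expected = np.sign(xty) * max(abs(xty) - rho, 0.0)
            assert b == pytest.approx(expected, abs=1e-12)
            # grid-search oracle over the scalar coefficient
            grid = np.linspace(-3, 3, 4001)
            losses = 0.5 * ((y[:, None] - np.outer(x, grid)) ** 2).sum(0) + rho * np.abs(grid)
            assert abs(grid[np.argmin(losses)] - b) < 2e-3

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_kkt_residual_small_at_convergence(self, seed):
        g = np.random.default_rng(seed)
        X = g.standard_normal((25, 8))
        y = g.standard_normal(25)
        rho = g.uniform(0.1, 3.0)
        cd_tol = 1e-9
        b = lasso_column(y, X, rho, cd_tol=cd_tol, cd_max_iter=5000)
        assert lasso_kkt_gap(y, X, b, rho) <= 10 * cd_tol * max(1, np.abs(X).max() ** 2 * 25)

    def test_warm_start_and_column_order_independence(self, rng):
        X = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 4))
        cols = [lasso_column(Y[:, j], X, 0.5, cd_tol=1e-12) for j in range(4)]
        cols_rev = [lasso_column(Y[:, j], X, 0.5, cd_tol=1e-12) for j in reversed(range(4))]
        for j in range(4):
            assert np.array_equal(cols[j], cols_rev[3 - j])

    def test_max_iter_warns_and_returns_best_iterate(self, rng):
        X = rng.standard_normal((40, 10))
        y = rng.standard_normal(40)
        with pytest.warns(RuntimeWarning, match="cd_max_iter"):
            b = lasso_column(y, X, 0.01, cd_tol=1e-15, cd_max_iter=1)
        assert np.all(np.isfinite(b))


class TestNumericalRank:
    @pytest.mark.parametrize(
        "matrix, tol, expected",
        [
            (np.zeros((4, 3)), 1e-8, 0),
            (np.eye(5), 1e-8, 5),
            (np.diag([10.0, 1e-12]), 1e-8, 1),
        ],
    )
    def test_thresholding_definition(self, matrix, tol, expected):
        assert numerical_rank(matrix, tol) == expected

    def test_accepts_low_rank_component(self):
        L = slrr.LowRankComponent(values=np.eye(3))
        assert numerical_rank(L, 1e-8) == 3


class TestFit:
    def test_dominating_penalties_zero_solution(self, rng):
        Y = rng.standard_normal((10, 6))
        X = np.zeros((10, 4))
        lam = np.linalg.svd(Y - Y.mean(0), compute_uv=False)[0] * 1.01
        res = fit(Y, X, FitConfig(rho=1.0, lam=lam))
        assert np.allclose(res.B.values, 0.0)
        assert np.allclose(res.L.values, 0.0)
        assert res.objective_trace[-1] == pytest.approx(0.5 * np.sum((Y - Y.mean(0)) ** 2))
        assert res.converged and res.n_iter <= 2

    def test_noiseless_sparse_signal_is_recovered(self, rng):
        # Y = X B* exactly, no confounder: the residual must shrink to ~0
        n, p, q = 100, 50, 20
        X = rng.binomial(1, 0.25, (n, p)).astype(float)
        B_star = np.zeros((p, q))
        idx = rng.choice(p * q, 30, replace=False)
        B_star[np.unravel_index(idx, (p, q))] = rng.standard_normal(30)
        Y = X @ B_star
        lam = np.linalg.svd(Y - Y.mean(0), compute_uv=False)[0]
        res = fit(Y, X, FitConfig(rho=1e-3, lam=lam, max_iter=200))
        Yc = Y - Y.mean(0)
        Xc = X - X.mean(0)
        rel = np.linalg.norm(Yc - Xc @ res.B.values) / np.linalg.norm(Y)
        assert rel < 0.05
        # every trace entry agrees with the standalone objective evaluator
        final = objective(Yc, Xc, res.B.values, res.L, res.config.rho, res.config.lam)
        assert res.objective_trace[-1] == pytest.approx(final, rel=1e-10)

    def test_objective_trace_non_increasing(self, easy_dataset):
        res = fit(easy_dataset.Y, easy_dataset.X, FitConfig(rho=0.5, lam=3.0))
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8)
        if res.converged:
            assert abs(trace[-2] - trace[-1]) < res.config.tol * max(1, abs(trace[-2]))

    def test_lam_limit_reduces_to_independent_lasso(self, easy_dataset):
        Y, X = easy_dataset.Y, easy_dataset.X
        cfg = FitConfig(rho=2.0, lam=1e12, cd_tol=1e-10)
        res = fit(Y, X, cfg)
        assert np.allclose(res.L.values, 0.0)
        Yc = Y.values - Y.values.mean(0)
        Xc = X.values - X.values.mean(0)
        for j in range(0, Y.n_genes, 5):
            direct = lasso_column(Yc[:, j], Xc, 2.0, cd_tol=1e-10, cd_max_iter=5000)
            assert np.abs(res.B.values[:, j] - direct).max() < 1e-6

    def test_rho_limit_reduces_to_svt_of_y(self, easy_dataset):
        Y, X = easy_dataset.Y, easy_dataset.X
        res = fit(Y, X, FitConfig(rho=1e12, lam=4.0))
        assert np.all(res.B.values == 0.0)
        Yc = Y.values - Y.values.mean(0)
        assert np.abs(res.L.values - svt_prox(Yc, 4.0).values).max() < 1e-6

    def test_single_unregularized_iteration_reproduces_residual(self, rng):
        Y = rng.standard_normal((8, 5))
        X = rng.standard_normal((8, 3))
        res = fit(Y, X, FitConfig(rho=0.0, lam=0.0, max_iter=1, center=False))
        # with both penalties off the first L-step absorbs Y - XB exactly
        assert np.allclose(Y - X @ res.B.values - res.L.values, 0.0, atol=1e-10)

    def test_misaligned_sample_ids_rejected(self, easy_dataset):
        Y = slrr.ExpressionMatrix(
            easy_dataset.Y.values,
            list(reversed(easy_dataset.Y.sample_ids)),
            easy_dataset.Y.gene_ids,
        )
        with pytest.raises(ValueError, match="sample_ids"):
            fit(Y, easy_dataset.X, FitConfig(rho=1.0, lam=1.0))

    def test_nan_inputs_rejected(self):
        Y = np.zeros((4, 2))
        X = np.zeros((4, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="preprocess"):
            fit(Y, X, FitConfig(rho=1.0, lam=1.0))

    def test_result_carries_ids_and_spectrum(self, easy_dataset, easy_fit):
        assert easy_fit.B.site_ids == easy_dataset.X.site_ids
        assert easy_fit.B.gene_ids == easy_dataset.Y.gene_ids
        sv = np.linalg.svd(easy_fit.L.values, compute_uv=False)
        kept = easy_fit.L.singular_values
        assert np.allclose(sv[: len(kept)], kept, atol=1e-8)


class TestPenaltySelection:
    def test_grid_anchored_at_data_scale(self, easy_dataset):
        rhos, lams = slrr.penalty_grid(easy_dataset.Y, easy_dataset.X)
        Yc = easy_dataset.Y.values - easy_dataset.Y.values.mean(0)
        Xc = easy_dataset.X.values - easy_dataset.X.values.mean(0)
        assert rhos[0] == pytest.approx(np.abs(Xc.T @ Yc).max())
        assert np.all(np.diff(rhos) < 0) and np.all(np.diff(lams) < 0)
        # rho_max forces an all-zero B
        res = fit(easy_dataset.Y, easy_dataset.X, FitConfig(rho=rhos[0] * 1.001, lam=lams[0]))
        assert res.B.nnz == 0

    def test_selector_returns_grid_member_with_table(self, easy_dataset):
        rho, lam, table = slrr.select_penalties(easy_dataset.Y, easy_dataset.X)
        assert {"rho", "lam", "score", "nnz", "rank"} <= set(table.columns)
        assert table["score"].iloc[0] == table["score"].min()
        assert (table["rho"] == rho).any() and (table["lam"] == lam).any()
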