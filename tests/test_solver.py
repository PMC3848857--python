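from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mircontext as mc
from mircontext.solver import RegressionConfig, select_stable_alpha

from _oracles import elastic_net_oracle
from conftest import random_regression

TIGHT = RegressionConfig(tol=1e-12, max_iter=100_000, standardize=False)


class TestSoftThreshold:
    @given(st.floats(-100, 100), st.floats(0, 100))
    @settings(deadline=None, max_examples=50)
    def test_matches_definition(self, z, gamma):
        got = mc.soft_threshold(z, gamma)
        assert got == pytest.approx(np.sign(z) * max(abs(z) - gamma, 0.0))

    def test_examples(self):
        assert mc.soft_threshold(3.0, 1.0) == 2.0
        assert mc.soft_threshold(-0.5, 1.0) == 0.0
        assert mc.soft_threshold(-2.5, 0.0) == -2.5

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            mc.soft_threshold(1.0, -0.1)


class TestCoordinateDescent:
    def test_unpenalized_fit_matches_least_squares(self):
        X, y = random_regression(0, n=40, p=6)
        fit = mc.coordinate_descent(X, y, 0.0, 0.6, TIGHT)
        Z = np.column_stack([np.ones(len(y)), X])
        coef = np.linalg.lstsq(Z, y, rcond=None)[0]
        assert fit.intercept == pytest.approx(coef[0], abs=1e-6)
        assert np.allclose(fit.beta, coef[1:], atol=1e-6)

    def test_lambda_at_lambda_max_gives_exact_zero(self):
        X, y = random_regression(1)
        lmax = mc.compute_lambda_max(X, y, 1.0, standardize=False)
        fit = mc.coordinate_descent(X, y, lmax, 1.0, TIGHT)
        assert np.all(fit.beta == 0.0)
        assert fit.intercept == pytest.approx(y.mean())

    def test_just_below_lambda_max_activates_a_coefficient(self):
        X, y = random_regression(2)
        lmax = mc.compute_lambda_max(X, y, 1.0, standardize=False)
        fit = mc.coordinate_descent(X, y, 0.99 * lmax, 1.0, TIGHT)
        assert fit.n_nonzero >= 1

    @pytest.mark.parametrize("seed,alpha", [(1, 0.6), (2, 1.0), (3, 0.3)])
    def test_matches_convex_oracle(self, seed, alpha):
        X, y = random_regression(seed, n=30, p=8)
        lam = 0.1
        fit = mc.coordinate_descent(X, y, lam, alpha, TIGHT)
        beta_o, b0_o = elastic_net_oracle(X, y, lam, alpha)
        obj = mc.elastic_net_objective(X, y, fit.beta, fit.intercept, lam, alpha)
        obj_o = mc.elastic_net_objective(X, y, beta_o, b0_o, lam, alpha)
        assert abs(obj - obj_o) < 1e-6
        assert np.max(np.abs(fit.beta - beta_o)) < 1e-4

    def test_ridge_limit_matches_closed_form(self):
        X, y = random_regression(4, n=50, p=10)
        lam = 0.7
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        n = len(y)
        beta_cf = np.linalg.solve(Xc.T @ Xc / n + lam * np.eye(10), Xc.T @ yc / n)
        fit = mc.coordinate_descent(Xc, yc, lam, 0.0, TIGHT)
        assert np.max(np.abs(fit.beta - beta_cf)) < 1e-6

    def test_standardized_coefficients_reported_on_original_scale(self):
        X, y = random_regression(5, n=60, p=5)
        X_scaled = X * np.array([1.0, 10.0, 0.1, 5.0, 2.0])
        cfg = RegressionConfig(tol=1e-12, max_iter=100_000, standardize=True)
        fit = mc.coordinate_descent(X_scaled, y, 0.05, 0.6, cfg)
        # predictions must be computed on the original scale without extra work
        resid = y - fit.predict(X_scaled)
        assert resid @ resid / len(y) < np.var(y)

    def test_constant_column_dropped_with_warning(self):
        X, y = random_regression(6, n=30, p=4)
        X[:, 2] = 3.14
        with pytest.warns(UserWarning, match="constant predictor"):
            fit = mc.coordinate_descent(X, y, 0.1, 0.6)
        assert fit.beta[2] == 0.0

    def test_nonfinite_input_rejected(self):
        X, y = random_regression(7)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mc.coordinate_descent(X, y, 0.1, 0.6)

    def test_objective_never_increases_across_sweeps(self):
        X, y = random_regression(8, n=25, p=6)
        objs = []
        for k in range(1, 12):
            cfg = RegressionConfig(tol=1e-16, max_iter=k, standardize=False)
            with pytest.warns(UserWarning):
                fit = mc.coordinate_descent(X, y, 0.05, 0.6, cfg)
            objs.append(mc.elastic_net_objective(X, y, fit.beta, fit.intercept, 0.05, 0.6))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_warm_start_converges_to_same_solution(self):
        X, y = random_regression(9)
        cold = mc.coordinate_descent(X, y, 0.1, 0.6, TIGHT)
        warm = mc.coordinate_descent(X, y, 0.1, 0.6, TIGHT, warm_start=cold.beta)
        assert np.allclose(cold.beta, warm.beta, atol=1e-8)
        assert warm.n_iter <= cold.n_iter

    def test_sparsity_nonincreasing_along_lasso_path(self):
        for seed in range(5):
            X, y = random_regression(seed, n=40, p=12, sparsity=4)
            lmax = mc.compute_lambda_max(X, y, 1.0, standardize=False)
            nnz = []
            for lam in mc.lambda_path(lmax, 25, 1e-3):
                fit = mc.coordinate_descent(X, y, lam, 1.0, TIGHT)
                nnz.append(fit.n_nonzero)
            violations = sum(b < a for a, b in zip(nnz, nnz[1:]))
            assert violations <= 1  # rare exact ties allowed


class TestLambdaMaxAndPath:
    def test_hand_computed_lambda_max(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        assert mc.compute_lambda_max(X, y, 1.0, standardize=False) == pytest.approx(1.0)

    def test_lambda_max_scales_with_response(self):
        X, y = random_regression(10)
        l1 = mc.compute_lambda_max(X, y, 1.0, standardize=False)
        l2 = mc.compute_lambda_max(X, 2 * y, 1.0, standardize=False)
        assert l2 == pytest.approx(2 * l1)

    def test_alpha_floor_keeps_ridge_anchor_finite(self):
        X, y = random_regression(11)
        l_ridge = mc.compute_lambda_max(X, y, 0.0)
        assert np.isfinite(l_ridge)
        assert l_ridge == pytest.approx(mc.compute_lambda_max(X, y, 1.0) / 1e-3)

    def test_constant_response_rejected(self):
        X, _ = random_regression(12)
        with pytest.raises(ValueError, match="degenerate"):
            mc.compute_lambda_max(X, np.ones(len(X)), 1.0)

    def test_log_spacing(self):
        path = mc.lambda_path(1.0, 3, 0.01)
        assert np.allclose(path, [1.0, 0.1, 0.01])
        path = mc.lambda_path(2.5, 40, 1e-4)
        assert path[0] == pytest.approx(2.5) and path[-1] == pytest.approx(2.5e-4)
        assert np.all(np.diff(path) < 0)


class TestKfoldCV:
    def test_same_seed_identical_curve(self):
        X, y = random_regression(13, n=60, p=10)
        lmax = mc.compute_lambda_max(X, y, 0.6)
        path = mc.lambda_path(lmax, 20)
        a = mc.kfold_cv(X, y, 0.6, path, n_folds=5, seed=3)
        b = mc.kfold_cv(X, y, 0.6, path, n_folds=5, seed=3)
        assert a.lambda_min == b.lambda_min
        assert np.array_equal(a.mean_mse, b.mean_mse)

    def test_lambda_min_is_on_path_and_attains_minimum(self):
        X, y = random_regression(14, n=80, p=10)
        lmax = mc.compute_lambda_max(X, y, 0.6)
        path = mc.lambda_path(lmax, 30)
        curve = mc.kfold_cv(X, y, 0.6, path, n_folds=5, seed=0)
        assert curve.lambda_min in curve.lambdas
        k = int(np.flatnonzero(curve.lambdas == curve.lambda_min)[0])
        assert curve.mean_mse[k] == curve.mean_mse.min()

    def test_two_fold_toy_matches_hand_arithmetic(self):
        # 4 samples, 1 predictor; lambda huge so each fold predicts the
        # training mean; held-out MSE is computable by hand.
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 1.0, 2.0, 4.0])
        lam = 1e6
        fold = mc.solver._stratified_folds(y, 2, seed=0)
        expected = []
        for f in (0, 1):
            tr, te = fold != f, fold == f
            mu = y[tr].mean()
            expected.append(np.mean((y[te] - mu) ** 2))
        curve = mc.kfold_cv(X, y, 1.0, np.array([lam]), n_folds=2, seed=0)
        assert curve.mean_mse[0] == pytest.approx(np.mean(expected))

    def test_stratification_puts_members_in_every_fold(self):
        y = np.array([1.0] * 10 + [0.0] * 90)
        fold = mc.solver._stratified_folds(y, 10, seed=1)
        for f in range(10):
            assert y[fold == f].sum() == 1


class TestOptimizeAlpha:
    def test_stabilization_rule_on_constructed_table(self):
        alphas = [0.2, 0.4, 0.6, 0.8, 1.0]
        lmins = [5.0, 2.0, 1.00, 1.01, 1.00]
        assert select_stable_alpha(alphas, lmins) == 0.6

    def test_never_stable_returns_none_then_fallback(self):
        alphas = [0.2, 0.4, 0.6, 0.8, 1.0]
        lmins = [16.0, 8.0, 4.0, 2.0, 1.0]
        assert select_stable_alpha(alphas, lmins) is None

    def test_single_element_grid(self):
        assert select_stable_alpha([0.5], [2.0]) == 0.5

    def test_search_runs_end_to_end(self):
        X, y = random_regression(15, n=60, p=8)
        cfg = RegressionConfig(
            alpha="auto", alpha_grid=(0.2, 0.6, 1.0), n_lambda=15, n_folds=4, seed=2
        )
        alpha_star, table = mc.optimize_alpha(X, y, cfg)
        assert alpha_star in (0.2, 0.6, 1.0)
        assert list(table.columns) == ["alpha", "lambda_min"] and len(table) == 3


class TestAgainstScikitLearn:
    """Independent cross-check against a mature elastic-net implementation
    that uses the same objective convention."""

    @pytest.mark.parametrize("alpha", [0.3, 0.6, 1.0])
    def test_coefficients_agree(self, alpha):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = random_regression(16, n=50, p=10)
        lam = 0.08
        ours = mc.coordinate_descent(X, y, lam, alpha, TIGHT)
        ref = sklearn.ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-12, max_iter=100_000
        ).fit(X, y)
        assert np.max(np.abs(ours.beta - ref.coef_)) < 1e-5
        assert ours.intercept == pytest.approx(ref.intercept_, abs=1e-5)
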