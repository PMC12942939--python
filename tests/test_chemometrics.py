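"""PLSR and epsilon-SVR against independent oracles (OLS, KKT, brute-force CV)."""

import numpy as np
import pytest

from ramanquant.chemometrics import (
    fit_plsr,
    fit_svr,
    grid_search_svr,
    predict,
    select_plsr_components,
    svr_objectives,
)
from ramanquant.datasets import kfold_indices
from ramanquant.exceptions import ConfigError, ValidationError
from ramanquant.simulate import default_profiles, make_mixture_fixture


class TestPLSR:
    def test_rank_one_relation_needs_one_component(self):
        # only one channel varies; y is affine in it
        rng = np.random.default_rng(0)
        X = np.full((12, 6), 3.0)
        X[:, 2] = rng.uniform(0, 1, 12)
        y = 2.5 * X[:, 2] - 1.0
        model = fit_plsr(X, y, 1)
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_full_rank_equals_ols(self, rng):
        # oracle: normal-equations OLS on the centered data
        X = rng.standard_normal((30, 5))
        y = X @ rng.standard_normal(5) + 0.3 * rng.standard_normal(30)
        model = fit_plsr(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ (y - y.mean()))
        ols = Xc @ beta + y.mean()
        assert np.allclose(model.predict(X), ols, atol=1e-6)

    def test_scores_orthogonal(self, rng):
        X = rng.standard_normal((25, 10))
        y = rng.standard_normal(25)
        model = fit_plsr(X, y, 6)
        G = model.scores.T @ model.scores
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(G))

    def test_matches_independent_nipals_implementation(self, rng):
        # cross-check against scikit-learn's PLS (independent implementation)
        from sklearn.cross_decomposition import PLSRegression

        X = rng.standard_normal((30, 12))
        y = X @ rng.standard_normal(12) + 0.1 * rng.standard_normal(30)
        for a in (1, 3, 6):
            mine = fit_plsr(X, y, a).predict(X)
            ref = PLSRegression(n_components=a, scale=False).fit(
                X, y.reshape(-1, 1)).predict(X).ravel()
            assert np.allclose(mine, ref, atol=1e-8)

    def test_two_profile_mixture_recovery(self):
        profiles = default_profiles(150)
        X, y = make_mixture_fixture(60, profiles, noise_sd=0.0, seed=3)
        model = fit_plsr(X[:40], y[:40], 2)
        resid = y[40:] - model.predict(X[40:])
        ss_tot = np.sum((y[40:] - y[40:].mean()) ** 2)
        r2 = 1 - np.sum(resid ** 2) / ss_tot
        assert r2 >= 0.999

    def test_y_shift_invariance(self, rng):
        X = rng.standard_normal((20, 8))
        y = rng.standard_normal(20)
        a = fit_plsr(X, y, 3).predict(X)
        b = fit_plsr(X, y + 5.0, 3).predict(X)
        assert np.allclose(b, a + 5.0, atol=1e-9)

    def test_invalid_component_count(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        with pytest.raises(ConfigError):
            fit_plsr(X, y, 5)


class TestPLSRSelection:
    def test_noiseless_rank_two_selects_enough(self):
        profiles = default_profiles(100)
        X, y = make_mixture_fixture(50, profiles, noise_sd=0.0, seed=1)
        best, curve = select_plsr_components(X, y, k_folds=5, max_components=6, seed=2)
        assert best >= 2
        assert curve[best - 1] < 1e-6

    def test_single_candidate(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        best, _ = select_plsr_components(X, y, max_components=1, seed=0)
        assert best == 1

    def test_selection_matches_bruteforce_cv(self, rng):
        # oracle: recompute the CV curve by hand with the same fold engine
        X = rng.standard_normal((24, 6))
        y = X @ rng.standard_normal(6) + 0.5 * rng.standard_normal(24)
        best, curve = select_plsr_components(X, y, k_folds=4, max_components=4, seed=5)
        folds = kfold_indices(24, 4, 5)
        manual = np.zeros(4)
        for fold in folds:
            mask = np.ones(24, dtype=bool)
            mask[fold] = False
            for a in range(1, 5):
                m = fit_plsr(X[mask], y[mask], a)
                manual[a - 1] += np.mean((y[fold] - m.predict(X[fold])) ** 2) / len(folds)
        assert np.allclose(curve, manual, rtol=1e-12)
        assert best == int(np.argmin(manual)) + 1

    def test_deterministic(self, rng):
        X = rng.standard_normal((20, 5))
        y = rng.standard_normal(20)
        a = select_plsr_components(X, y, seed=9)
        b = select_plsr_components(X, y, seed=9)
        assert a[0] == b[0] and np.array_equal(a[1], b[1])

    def test_too_few_samples(self, rng):
        X = rng.standard_normal((4, 3))
        with pytest.raises(ConfigError):
            select_plsr_components(X, rng.standard_normal(4), k_folds=5)


class TestSVR:
    def test_flat_solution_inside_tube(self, rng):
        X = rng.standard_normal((3, 2))
        y = np.array([1.0, 1.1, 0.9])
        model = fit_svr(X, y, kernel="linear", C=1.0, epsilon=0.2)
        assert model.n_support == 0
        preds = model.predict(X)
        assert np.all(np.abs(preds[:, None] - y[None, :]) <= 0.2 + 1e-3)

    def test_zero_slack_linear_fit(self, rng):
        X = rng.standard_normal((20, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 3.0
        model = fit_svr(X, y, kernel="linear", C=1e4, epsilon=0.01)
        assert np.max(np.abs(y - model.predict(X))) <= 0.01 + 1e-3

    def test_gaussian_kernel_self_similarity(self, rng):
        X = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        model = fit_svr(X, y, kernel="gaussian", C=1.0, epsilon=0.1, gamma=0.5)
        Xs = model._standardize(X)
        K = model._kernel_matrix(Xs, Xs)
        assert np.allclose(np.diag(K), 1.0, atol=1e-12)

    def test_kkt_bounds_and_duality_gap(self, rng):
        X = rng.standard_normal((40, 6))
        y = X @ rng.standard_normal(6) + 0.2 * rng.standard_normal(40)
        for kernel, gamma in (("linear", None), ("gaussian", 0.2)):
            model = fit_svr(X, y, kernel=kernel, C=10.0, epsilon=0.05, gamma=gamma)
            assert np.all(np.abs(model.dual_coef) <= model.C + 1e-9)
            primal, dual = svr_objectives(model, X, y)
            assert primal - dual <= 1e-3 * (1 + abs(primal))

    def test_epsilon_monotone_sparsity(self, rng):
        X = rng.standard_normal((50, 4))
        y = X @ rng.standard_normal(4) + 0.3 * rng.standard_normal(50)
        counts = [fit_svr(X, y, kernel="linear", C=10.0, epsilon=e).n_support
                  for e in (0.01, 0.05, 0.2, 0.5, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_y_shift_invariance(self, rng):
        X = rng.standard_normal((25, 3))
        y = X @ np.array([1.0, 0.5, -1.0]) + 0.1 * rng.standard_normal(25)
        a = fit_svr(X, y, kernel="linear", C=10.0, epsilon=0.05).predict(X)
        b = fit_svr(X, y + 4.0, kernel="linear", C=10.0, epsilon=0.05).predict(X)
        assert np.allclose(b, a + 4.0, atol=1e-4)

    def test_parameter_validation(self, rng):
        X = rng.standard_normal((5, 2))
        y = rng.standard_normal(5)
        with pytest.raises(ConfigError):
            fit_svr(X, y, C=-1.0)
        with pytest.raises(ConfigError):
            fit_svr(X, y, kernel="gaussian", gamma=-0.1)
        with pytest.raises(ConfigError):
            fit_svr(X, y, kernel="poly")


class TestGridSearch:
    def test_single_point_grid(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        best, table = grid_search_svr(
            X, y, grids={"C": [1.0], "epsilon": [0.1], "gamma": [0.5]},
            kernel="gaussian", k_folds=4, seed=0)
        assert best == {"C": 1.0, "epsilon": 0.1, "gamma": 0.5, "kernel": "gaussian"}
        assert len(table) == 1

    def test_picks_lower_cv_mse(self, rng):
        # oracle: compute both candidate CV MSEs directly and compare
        X = rng.standard_normal((30, 3))
        y = X @ np.array([2.0, -1.0, 0.5]) + 0.05 * rng.standard_normal(30)
        grid = {"C": [0.01, 100.0], "epsilon": [0.01]}
        best, table = grid_search_svr(X, y, grids=grid, kernel="linear",
                                      k_folds=5, seed=3)
        folds = kfold_indices(30, 5, 3)
        manual = {}
        for C in grid["C"]:
            mses = []
            for fold in folds:
                mask = np.ones(30, dtype=bool)
                mask[fold] = False
                m = fit_svr(X[mask], y[mask], kernel="linear", C=C, epsilon=0.01)
                mses.append(np.mean((y[fold] - m.predict(X[fold])) ** 2))
            manual[C] = np.mean(mses)
        assert best["C"] == min(manual, key=manual.get)
        by_c = {row["C"]: row["mean_mse"] for row in table}
        for C in grid["C"]:
            assert by_c[C] == pytest.approx(manual[C], rel=1e-12)

    def test_deterministic_table(self, rng):
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        kw = dict(grids={"C": [0.1, 1.0], "epsilon": [0.1], "gamma": [0.1]},
                  k_folds=4, seed=6)
        _, t1 = grid_search_svr(X, y, **kw)
        _, t2 = grid_search_svr(X, y, **kw)
        assert t1 == t2

    def test_empty_grid_dimension(self, rng):
        X = rng.standard_normal((10, 2))
        with pytest.raises(ConfigError):
            grid_search_svr(X, rng.standard_normal(10), grids={"C": []})


class TestPredictContract:
    def test_exact_fit_restated(self, rng):
        X = np.full((10, 4), 1.0)
        X[:, 1] = rng.uniform(0, 1, 10)
        y = 3 * X[:, 1]
        model = fit_plsr(X, y, 1)
        assert np.allclose(predict(model, X), y, atol=1e-8)

    def test_single_row(self, rng):
        X = rng.standard_normal((10, 4))
        model = fit_plsr(X, rng.standard_normal(10), 2)
        assert predict(model, X[:1]).shape == (1,)

    def test_dimension_mismatch(self, rng):
        X = rng.standard_normal((10, 4))
        model = fit_plsr(X, rng.standard_normal(10), 2)
        with pytest.raises(ValidationError):
            predict(model, rng.standard_normal((3, 5)))
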