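"""The penalized logistic solver, its KKT certificates and penalty selection."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import binmrf as bm
from binmrf.errors import DegenerateOutcomeError, DegeneratePredictorError
from binmrf.lasso import information_criterion, kkt_violation


def nll_l1(y, X, params, lam):
    eta = params[0] + X @ params[1:]
    return -np.sum(y * eta - np.logaddexp(0, eta)) + lam * np.abs(params[1:]).sum()


class TestStandardize:
    def test_balanced_binary_column_maps_to_plus_minus_one(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        Xs, center, scale = bm.standardize(X)
        assert set(np.unique(Xs)) == {-1.0, 1.0}
        assert center[0] == 0.5 and scale[0] == 0.5

    def test_idempotent_on_standardized_input(self, logistic_problem):
        _, X = logistic_problem
        Xs, _, _ = bm.standardize(X)
        assert np.allclose(Xs, X, atol=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(DegeneratePredictorError, match="column 1"):
            bm.standardize(np.array([[1.0, 3.0], [2.0, 3.0]]))


class TestFit:
    def test_full_penalty_gives_intercept_only(self, logistic_problem):
        y, X = logistic_problem
        grid = bm.penalty_grid(y, X)
        fit = bm.fit_l1_logistic(y, X, grid.values[0])
        assert fit.active_set == frozenset()
        assert np.all(fit.coefficients == 0.0)
        assert fit.intercept == pytest.approx(math.log(y.mean() / (1 - y.mean())))

    def test_unpenalized_matches_convex_optimizer(self, logistic_problem):
        y, X = logistic_problem
        fit = bm.fit_l1_logistic(y, X, 0.0)
        res = minimize(
            lambda p: nll_l1(y, X, p, 0.0),
            np.zeros(X.shape[1] + 1),
            method="BFGS",
            tol=1e-12,
        )
        ours = np.r_[fit.intercept, fit.coefficients]
        assert np.abs(ours - res.x).max() < 1e-5

    @pytest.mark.parametrize("seed", range(5))
    def test_kkt_holds_along_path(self, seed):
        rng = np.random.default_rng(seed)
        n, m = 50, 4
        X = rng.normal(size=(n, m))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(n) < expit(X @ rng.normal(size=m))).astype(float)
        grid = bm.penalty_grid(y, X, size=30)
        for fit in bm.regularization_path(y, X, grid):
            assert (
                kkt_violation(y, X, fit.penalty, fit.intercept, fit.coefficients)
                <= 1e-6
            )

    def test_objective_matches_direct_minimization(self):
        """Penalized objective value agrees with a generic optimizer."""
        rng = np.random.default_rng(11)
        n, m = 40, 2
        X = rng.normal(size=(n, m))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(n) < expit(0.2 + X @ np.array([0.8, -0.4]))).astype(float)
        lam = 3.0
        fit = bm.fit_l1_logistic(y, X, lam)
        ours = nll_l1(y, X, np.r_[fit.intercept, fit.coefficients], lam)
        best = min(
            minimize(
                lambda p: nll_l1(y, X, p, lam),
                start,
                method="Powell",
                options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 10000},
            ).fun
            for start in (np.zeros(m + 1), np.array([0.2, 0.8, -0.4]))
        )
        assert ours <= best + 1e-4

    def test_degenerate_outcome_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DegenerateOutcomeError):
            bm.fit_l1_logistic(np.ones(10), X, 1.0)


class TestPath:
    def test_path_starts_empty_and_is_near_monotone(self, m6_data_1000):
        X = m6_data_1000.data.astype(float)
        y = X[:, 0]
        Xs, _, _ = bm.standardize(X[:, 1:])
        grid = bm.penalty_grid(y, Xs)
        path = bm.regularization_path(y, Xs, grid)
        sizes = [f.n_active for f in path]
        assert sizes[0] == 0
        steps = np.diff(sizes)
        assert (steps >= 0).mean() >= 0.95

    def test_penalized_objective_nonincreasing_along_path(self, logistic_problem):
        y, X = logistic_problem
        grid = bm.penalty_grid(y, X, size=40)
        vals = [
            nll_l1(y, X, np.r_[f.intercept, f.coefficients], f.penalty)
            for f in bm.regularization_path(y, X, grid)
        ]
        assert np.all(np.diff(vals) <= 1e-8)

    def test_smallest_penalty_approximates_unpenalized_fit(self, logistic_problem):
        y, X = logistic_problem
        grid = bm.penalty_grid(y, X)
        last = bm.regularization_path(y, X, grid)[-1]
        free = bm.fit_l1_logistic(y, X, 0.0)
        assert np.abs(last.coefficients - free.coefficients).max() < 0.02


class TestInformationCriteria:
    def test_formulas(self):
        assert information_criterion(-10.0, 3, 50, "aic") == pytest.approx(26.0)
        assert information_criterion(-10.0, 3, 100, "bic") == pytest.approx(
            20.0 + 3 * math.log(100)
        )

    def test_bic_never_larger_active_set_than_aic(self, m6):
        """BIC penalizes model size harder than AIC for n > 7."""
        wins = 0
        reps = 50
        for s in range(reps):
            data = bm.gibbs_sample(m6, 500, seed=20_000 + s)
            X = data.data.astype(float)
            y = X[:, 0]
            Xs, _, _ = bm.standardize(X[:, 1:])
            grid = bm.penalty_grid(y, Xs)
            path = bm.regularization_path(y, Xs, grid)
            sizes = {f.penalty: f.n_active for f in path}
            lam_a = bm.select_penalty_ic(y, Xs, grid, "aic", path=path)
            lam_b = bm.select_penalty_ic(y, Xs, grid, "bic", path=path)
            if sizes[lam_b] <= sizes[lam_a]:
                wins += 1
        assert wins / reps >= 0.90


class TestSelectPenaltyCV:
    def test_chosen_penalty_is_on_grid_and_null_data_stays_sparse(self):
        sparse = 0
        seeds = 20
        for s in range(seeds):
            rng = np.random.default_rng(300 + s)
            n, m = 800, 5
            X = rng.normal(size=(n, m))
            X = (X - X.mean(0)) / X.std(0)
            y = (rng.random(n) < 0.5).astype(float)
            grid = bm.penalty_grid(y, X)
            lam = bm.select_penalty_cv(y, X, grid, folds=10, seed=s)
            assert lam in grid.values
            if bm.fit_l1_logistic(y, X, lam).n_active <= 1:
                sparse += 1
        assert sparse / seeds >= 0.80

    def test_single_fold_rejected(self, logistic_problem):
        y, X = logistic_problem
        grid = bm.penalty_grid(y, X)
        with pytest.raises(ValueError):
            bm.select_penalty_cv(y, X, grid, folds=1)


class TestPenaltyForSize:
    def test_zero_target_rejected(self, logistic_problem):
        y, X = logistic_problem
        grid = bm.penalty_grid(y, X)
        with pytest.raises(ValueError):
            bm.penalty_for_size(y, X, grid, 0)

    def test_dominant_predictor_selected_alone_at_size_one(self):
        rng = np.random.default_rng(5)
        n = 500
        X = rng.normal(size=(n, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = (rng.random(n) < expit(2.5 * X[:, 2])).astype(float)
        grid = bm.penalty_grid(y, X)
        lam = bm.penalty_for_size(y, X, grid, 1)
        fit = bm.fit_l1_logistic(y, X, lam)
        assert fit.active_set == {"x2"}

    def test_contract_largest_penalty_reaching_size(self, m6_data_1000):
        X = m6_data_1000.data.astype(float)
        y = X[:, 1]
        Xs, _, _ = bm.standardize(np.delete(X, 1, axis=1))
        grid = bm.penalty_grid(y, Xs)
        path = bm.regularization_path(y, Xs, grid)
        lam = bm.penalty_for_size(y, Xs, grid, 2, path=path)
        assert lam in grid.values
        for lam_g, fit in zip(grid.values, path):
            if lam_g > lam:
                assert fit.n_active < 2
            if lam_g == lam:
                assert fit.n_active >= 2
                break

    def test_lambda_max_is_exact_selection_boundary(self):
        """The grid anchor is the smallest penalty with an empty active set:
        the fit is empty at λ_max and nonempty just below it."""
        for s in range(10):
            rng = np.random.default_rng(40_000 + s)
            n, m = 100, 3
            X = rng.normal(size=(n, m))
            X = (X - X.mean(0)) / X.std(0)
            y = (rng.random(n) < 0.5).astype(float)
            lam_max = bm.penalty_grid(y, X).values[0]
            assert bm.fit_l1_logistic(y, X, lam_max).n_active == 0
            assert bm.fit_l1_logistic(y, X, lam_max * 0.98).n_active >= 1
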