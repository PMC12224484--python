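"""Nested CV engine: plan structure, ridge fits vs an independent optimiser,
lambda selection rules and leak-free evaluation."""

import numpy as np
import pytest
from scipy.optimize import minimize

from connclass.cohort import CohortConfig, generate_cohort
from connclass.cv import (
    ConvergenceError,
    RidgeConfig,
    fit_lambda_path,
    fit_logistic_ridge,
    make_cv_plan,
    objective_gradient,
    run_nested_cv,
    select_lambda,
)
from connclass.features import AlignmentError, FeatureMatrix, ValidationError
from connclass.matching import MatchedPair, MatchedSample


def _sample(n_pairs):
    pairs = [
        MatchedPair(f"C{i:03d}", f"H{i:03d}", 0.0, 0.0) for i in range(n_pairs)
    ]
    return MatchedSample(phenotype="ever", ctq_threshold=None, pairs=pairs)


def _logistic_data(rng, n=60, p=5, beta_scale=2.0):
    x = rng.standard_normal((n, p))
    beta = beta_scale * rng.standard_normal(p)
    y = (x @ beta + 0.3 * rng.standard_normal(n) > 0).astype(int)
    return x, y


def _oracle_fit(x, y, lam):
    """Minimise the mean-log-loss ridge objective with a generic optimiser."""
    ypm = np.where(np.asarray(y) > 0, 1.0, -1.0)
    n, p = x.shape

    def objective(theta):
        b, beta = theta[0], theta[1:]
        margins = ypm * (x @ beta + b)
        return np.mean(np.logaddexp(0.0, -margins)) + lam * beta @ beta

    res = minimize(objective, np.zeros(p + 1), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    return res.x[0], res.x[1:]


class TestPlan:
    def test_thirty_pairs_give_balanced_folds(self):
        plan = make_cv_plan(_sample(30), 6, 5, seed=0)
        counts = np.bincount(plan.outer, minlength=6)
        assert counts.tolist() == [5] * 6
        for o in range(6):
            inner = plan.inner[o]
            assert (inner[plan.outer == o] == -1).all()
            assert np.bincount(inner[inner >= 0], minlength=5).tolist() == [5] * 5

    def test_every_pair_in_exactly_one_outer_fold(self):
        plan = make_cv_plan(_sample(47), 6, 5, seed=1)
        assert len(plan.outer) == 47
        assert set(plan.outer) == set(range(6))
        assert np.abs(np.diff(np.sort(np.bincount(plan.outer)))).max() <= 1

    def test_same_seed_same_plan(self):
        a = make_cv_plan(_sample(40), seed=9)
        b = make_cv_plan(_sample(40), seed=9)
        assert np.array_equal(a.outer, b.outer) and np.array_equal(a.inner, b.inner)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            make_cv_plan(_sample(5), 6, 5, seed=0)


class TestRidgeFit:
    @pytest.mark.parametrize("lam", [1e-2, 1.0, 50.0])
    def test_agrees_with_generic_convex_optimiser(self, rng, lam):
        x, y = _logistic_data(rng)
        model = fit_logistic_ridge(x, y, lam)
        b0, beta0 = _oracle_fit(x, y, lam)
        assert model.intercept == pytest.approx(b0, abs=1e-4)
        assert np.abs(model.coef - beta0).max() < 1e-4

    def test_separable_toy_reaches_perfect_training_accuracy(self):
        x = np.array([[1.0, 0.2], [2.0, -0.1], [-1.0, 0.1], [-2.0, 0.3]])
        y = np.array([1, 1, 0, 0])
        model = fit_logistic_ridge(x, y, 1e-3)
        assert model.accuracy(x, y) == 1.0
        b0, beta0 = _oracle_fit(x, y, 1e-3)
        assert np.abs(model.coef - beta0).max() < 1e-4

    def test_coefficient_norm_shrinks_along_lambda_path(self, rng):
        x, y = _logistic_data(rng)
        cfg = RidgeConfig()
        norms = [np.linalg.norm(m.coef) for m in fit_lambda_path(x, y, cfg)]
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 1e-2 * norms[0]  # heavy-shrinkage limit

    def test_first_order_optimality_at_solution(self, rng):
        x, y = _logistic_data(rng)
        cfg = RidgeConfig()
        model = fit_logistic_ridge(x, y, 0.5, cfg)
        gb, gbeta = objective_gradient(x, y, 0.5, model.intercept, model.coef)
        assert max(abs(gb), np.abs(gbeta).max()) < cfg.grad_tol

    def test_nonfinite_inputs_rejected(self, rng):
        x, y = _logistic_data(rng)
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_logistic_ridge(x, y, 1.0)

    def test_nonconvergence_reports_iteration_count(self, rng):
        x, y = _logistic_data(rng, n=200, p=50)
        cfg = RidgeConfig(max_iter=2, grad_tol=1e-10)
        with pytest.raises(ConvergenceError) as err:
            fit_logistic_ridge(x, y, 1e-3, cfg)
        assert err.value.n_iter >= 1


class TestSelectLambda:
    def test_single_value_grid(self, rng):
        x, y = _logistic_data(rng, n=50)
        cfg = RidgeConfig(lambdas=np.array([0.3]))
        inner = np.arange(25) % 5
        models = select_lambda(x, y, inner, cfg, np.arange(50) % 25)
        assert [m.lam for m in models] == [0.3] * 5

    def test_ties_resolve_to_largest_lambda(self, rng):
        # one dominant feature: every lambda attains the same validation accuracy
        n = 40
        x = 0.01 * rng.standard_normal((n, 2))
        x[:, 0] = np.r_[np.ones(n // 2), -np.ones(n // 2)] * (1 + 0.01 * rng.random(n))
        y = (x[:, 0] > 0).astype(int)
        cfg = RidgeConfig(lambdas=np.logspace(-3, 3, 5))
        inner = np.arange(n // 2) % 5
        models = select_lambda(x, y, inner, cfg, np.arange(n) % (n // 2))
        assert all(m.lam == 1e3 for m in models)
        assert all(m.validation_accuracy == 1.0 for m in models)


class TestNestedCV:
    @staticmethod
    def _feature_matrix(sample, p, rng, signal=0.0):
        ids = sample.subject_ids
        x = rng.standard_normal((len(ids), p))
        y = np.r_[np.ones(sample.n_pairs), np.zeros(sample.n_pairs)]
        x[:, 0] += signal * (2 * y - 1)
        return FeatureMatrix(
            subject_ids=tuple(ids),
            values=x,
            col_modality=np.array(["corr"] * p, dtype=object),
            col_edge=np.arange(p),
        )

    def test_thirty_models_and_accuracies(self, rng):
        sample = _sample(30)
        fm = self._feature_matrix(sample, 12, rng, signal=2.5)
        plan = make_cv_plan(sample, seed=2)
        res = run_nested_cv(fm, sample, plan)
        assert len(res.models) == 30
        assert res.accuracies.shape == (30,)
        assert np.all((res.accuracies >= 0) & (res.accuracies <= 1))
        assert res.mean_accuracy > 0.85  # strong univariate signal

    def test_no_outer_test_subject_in_training_set(self, rng):
        sample = _sample(24)
        fm = self._feature_matrix(sample, 6, rng)
        plan = make_cv_plan(sample, seed=3)
        res = run_nested_cv(fm, sample, plan)
        ids = np.array(sample.subject_ids)
        row_pair = np.r_[np.arange(24), np.arange(24)]
        for model in res.models:
            test_ids = set(ids[plan.outer[row_pair] == model.outer_fold])
            assert not test_ids & set(model.train_ids)
            val_ids = set(ids[plan.inner[model.outer_fold][row_pair] == model.inner_fold])
            assert not val_ids & set(model.train_ids)

    def test_missing_subject_features_rejected(self, rng):
        sample = _sample(12)
        fm = self._feature_matrix(sample, 4, rng)
        fm = FeatureMatrix(
            subject_ids=fm.subject_ids[:-1],
            values=fm.values[:-1],
            col_modality=fm.col_modality,
            col_edge=fm.col_edge,
        )
        plan = make_cv_plan(sample, seed=0)
        with pytest.raises(AlignmentError):
            run_nested_cv(fm, sample, plan)

    def test_large_planted_effect_classifies_above_ninety_percent(self):
        """Connectome effect of 0.8 z at 300 pairs is essentially separable."""
        from connclass.pipeline import ExperimentGrid, run_cell

        config = CohortConfig(
            n_subjects=3000, seed=21, functional_nodes=20,
            subnetwork_sizes=(4, 4, 4, 4, 2, 2), ts_length=120,
            delta=0.8, ctq_slope=0.0, effect_phenotype="ever",
        )
        cohort = generate_cohort(config)
        grid = ExperimentGrid(cohort=config, phenotypes=("ever",),
                              n_pairs=300, seed=21)
        cell = run_cell(cohort, grid, "ever", "corr", None)
        assert cell.mean_accuracy > 0.9
        chosen = {m.lam for m in cell.cv.models}
        assert len(chosen) >= 1  # lambda logged per fold
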