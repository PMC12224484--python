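"""Nested cross-validated logistic ridge classification.

The classifier is L2-penalised logistic regression minimising

    (1/n) * sum_i log(1 + exp(-y_i (beta . x_i + b))) + lambda * ||beta||^2

with an unpenalised intercept. Model selection runs as a pair-level nested
cross-validation: pairs are split into 6 outer folds; within each outer
training set (5/6 of pairs) an inner 5-fold split selects, per inner fold,
the lambda from a log-spaced grid that maximises inner-validation accuracy.
Each of the 6 x 5 = 30 inner-optimal models is then evaluated on its
untouched outer test fold, giving 30 test accuracies whose mean is the
performance estimate. Members of a matched pair always share fold
assignments, so every training, validation and test set stays balanced.

Z-normalisation statistics are fitted on each inner-training set only and
reused for the corresponding validation and outer-test evaluations; outer
test subjects never influence normalisation or lambda selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import AlignmentError, FeatureMatrix, ValidationError, apply_znorm, fit_znorm
from .matching import MatchedSample

__all__ = [
    "RidgeConfig",
    "FittedModel",
    "CVPlan",
    "CVResult",
    "ConvergenceError",
    "PlanError",
    "default_lambda_grid",
    "make_cv_plan",
    "fit_logistic_ridge",
    "fit_lambda_path",
    "objective_gradient",
    "select_lambda",
    "run_nested_cv",
]


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, n_iter: int):
        super().__init__(f"{message} (after {n_iter} iterations)")
        self.n_iter = n_iter


class PlanError(ValueError):
    pass


def default_lambda_grid(n_points: int = 13, low: float = 1e-3, high: float = 1e3) -> np.ndarray:
    """Log-spaced ridge penalties; the default covers 1e-3..1e3 in half decades."""
    return np.logspace(np.log10(low), np.log10(high), n_points)


@dataclass
class RidgeConfig:
    lambdas: np.ndarray = field(default_factory=default_lambda_grid)
    tol: float = 1e-6        # solver tolerance passed to the optimiser
    grad_tol: float = 1e-3   # acceptance bound on the objective gradient inf-norm
    max_iter: int = 3000

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if (self.lambdas <= 0).any():
            raise ValidationError("all lambdas must be positive")
        if (np.diff(self.lambdas) <= 0).any():
            raise ValidationError("lambda grid must be strictly ascending")


@dataclass
class FittedModel:
    lam: float
    intercept: float
    coef: np.ndarray
    train_ids: tuple[str, ...] = ()
    outer_fold: int = -1
    inner_fold: int = -1
    n_iter: int = 0
    validation_accuracy: float = float("nan")

    def decision(self, x: np.ndarray) -> np.ndarray:
        return x @ self.coef + self.intercept

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.decision(x) > 0).astype(int)

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == np.asarray(y)))


@dataclass
class CVPlan:
    """Pair-level fold assignments.

    ``outer[p]`` is the outer fold (0..n_outer-1) of pair p. ``inner[o][p]``
    is the inner fold (0..n_inner-1) of pair p within outer-training set o,
    or -1 if pair p belongs to outer test fold o.
    """

    n_pairs: int
    n_outer: int
    n_inner: int
    outer: np.ndarray
    inner: np.ndarray  # (n_outer, n_pairs)
    seed: int


def make_cv_plan(
    sample: MatchedSample, n_outer: int = 6, n_inner: int = 5, seed: int = 0
) -> CVPlan:
    """Random balanced pair-level assignment (fold sizes differ by <= 1)."""
    n_pairs = sample.n_pairs
    if n_pairs < n_outer:
        raise ValidationError(f"{n_pairs} pairs cannot fill {n_outer} outer folds")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 10)))
    outer = np.empty(n_pairs, dtype=int)
    outer[rng.permutation(n_pairs)] = np.arange(n_pairs) % n_outer
    inner = np.full((n_outer, n_pairs), -1, dtype=int)
    for o in range(n_outer):
        train_pairs = np.flatnonzero(outer != o)
        if len(train_pairs) < n_inner:
            raise ValidationError("outer training set smaller than the inner fold count")
        shuffled = rng.permutation(train_pairs)
        inner[o, shuffled] = np.arange(len(shuffled)) % n_inner
    return CVPlan(n_pairs=n_pairs, n_outer=n_outer, n_inner=n_inner,
                  outer=outer, inner=inner, seed=seed)


# ---------------------------------------------------------------------------
# penalised logistic fits
# ---------------------------------------------------------------------------

def _as_pm1(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    out = np.where(y > 0, 1.0, -1.0)
    return out


def objective_gradient(
    x: np.ndarray, y: np.ndarray, lam: float, intercept: float, coef: np.ndarray
) -> tuple[float, np.ndarray]:
    """Gradient of the mean-log-loss ridge objective at (intercept, coef)."""
    ypm = _as_pm1(y)
    margins = ypm * (x @ coef + intercept)
    # sigma(-m) computed stably
    s = np.where(margins >= 0, np.exp(-margins) / (1 + np.exp(-margins)),
                 1.0 / (1 + np.exp(margins)))
    w = -ypm * s / len(ypm)
    return float(w.sum()), x.T @ w + 2.0 * lam * coef


def _fit_estimator(x: np.ndarray, y01: np.ndarray, lam: float, cfg: RidgeConfig,
                   est: LogisticRegression | None) -> LogisticRegression:
    c = 1.0 / (2.0 * len(y01) * lam)
    if est is None:
        est = LogisticRegression(
            C=c, solver="lbfgs", tol=cfg.tol,
            max_iter=cfg.max_iter, warm_start=True,
        )
    else:
        est.C = c
    est.fit(x, y01)
    return est


def _check_converged(x, y, lam, model: FittedModel, cfg: RidgeConfig) -> None:
    gb, gbeta = objective_gradient(x, y, lam, model.intercept, model.coef)
    gnorm = max(abs(gb), float(np.abs(gbeta).max()))
    if gnorm > cfg.grad_tol:
        raise ConvergenceError(
            f"ridge fit at lambda={lam:g} stopped with gradient inf-norm "
            f"{gnorm:.3g} > {cfg.grad_tol:g}", model.n_iter)


def fit_logistic_ridge(
    x: np.ndarray, y: np.ndarray, lam: float, cfg: RidgeConfig | None = None
) -> FittedModel:
    """Fit one L2-penalised logistic model; intercept unpenalised.

    ``y`` may be 0/1 or +/-1 coded. Raises :class:`ConvergenceError` if the
    first-order optimality check fails.
    """
    cfg = cfg or RidgeConfig()
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in features or labels")
    if lam <= 0:
        raise ValidationError("lambda must be positive")
    y01 = (_as_pm1(y) > 0).astype(int)
    est = _fit_estimator(x, y01, lam, cfg, None)
    model = FittedModel(lam=float(lam), intercept=float(est.intercept_[0]),
                        coef=est.coef_[0].copy(), n_iter=int(est.n_iter_[0]))
    _check_converged(x, y, lam, model, cfg)
    return model


def fit_lambda_path(
    x: np.ndarray, y: np.ndarray, cfg: RidgeConfig
) -> list[FittedModel]:
    """Fit the whole lambda grid, warm-starting along the ascending path."""
    x = np.asarray(x, dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("non-finite values in features or labels")
    y01 = (_as_pm1(y) > 0).astype(int)
    est = None
    models = []
    for lam in cfg.lambdas:
        est = _fit_estimator(x, y01, lam, cfg, est)
        model = FittedModel(lam=float(lam), intercept=float(est.intercept_[0]),
                            coef=est.coef_[0].copy(), n_iter=int(est.n_iter_[0]))
        _check_converged(x, y, lam, model, cfg)
        models.append(model)
    return models


def select_lambda(
    x: np.ndarray,
    y: np.ndarray,
    inner_assign: np.ndarray,
    cfg: RidgeConfig,
    row_pair: np.ndarray,
) -> list[FittedModel]:
    """Per-inner-fold lambda selection on one outer training set.

    ``inner_assign`` gives the inner fold of every pair; ``row_pair`` maps
    each row of ``x`` to its pair. For each inner fold m, every grid lambda
    is fitted on the inner-training rows (z-normalised on those rows) and
    scored on the inner-validation rows; the accuracy-maximising model is
    kept, ties resolved toward the largest lambda.
    """
    models = []
    for m in range(int(inner_assign.max()) + 1):
        val_rows = np.flatnonzero(inner_assign[row_pair] == m)
        train_rows = np.flatnonzero(
            (inner_assign[row_pair] != m) & (inner_assign[row_pair] >= 0))
        if len(val_rows) == 0:
            raise PlanError(f"inner fold {m} has an empty validation set")
        stats = fit_znorm(x[train_rows])
        xt = apply_znorm(x[train_rows], stats)
        xv = apply_znorm(x[val_rows], stats)
        path = fit_lambda_path(xt, y[train_rows], cfg)
        accs = np.array([mod.accuracy(xv, y[val_rows]) for mod in path])
        best = int(np.flatnonzero(accs == accs.max()).max())  # tie -> largest lambda
        chosen = path[best]
        chosen.inner_fold = m
        chosen.validation_accuracy = float(accs[best])
        chosen._znorm = stats  # reused for the outer-test evaluation
        models.append(chosen)
    return models


@dataclass
class CVResult:
    """All 30 inner-optimal models with their outer-test accuracies."""

    models: list[FittedModel]
    accuracies: np.ndarray           # (n_outer * n_inner,)
    plan: CVPlan

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def se_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1) / np.sqrt(len(self.accuracies)))

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([m.lam for m in self.models])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "outer_fold": [m.outer_fold for m in self.models],
                "inner_fold": [m.inner_fold for m in self.models],
                "lambda": self.lambdas,
                "validation_accuracy": [m.validation_accuracy for m in self.models],
                "test_accuracy": self.accuracies,
            }
        )


def run_nested_cv(
    fm: FeatureMatrix,
    sample: MatchedSample,
    plan: CVPlan,
    cfg: RidgeConfig | None = None,
) -> CVResult:
    """Execute the nested cross-validation on a matched sample.

    Rows are looked up by subject id (raises :class:`AlignmentError` when a
    subject has no features). Cases are labelled 1 and controls 0.
    """
    cfg = cfg or RidgeConfig()
    if plan.n_pairs != sample.n_pairs:
        raise PlanError("plan and sample pair counts differ")
    case_rows = fm.rows_for(sample.case_ids)
    ctrl_rows = fm.rows_for(sample.control_ids)
    rows = np.concatenate([case_rows, ctrl_rows])
    y = np.concatenate([np.ones(sample.n_pairs), np.zeros(sample.n_pairs)])
    row_pair = np.concatenate([np.arange(sample.n_pairs), np.arange(sample.n_pairs)])
    x = fm.values[rows]
    ids = np.array(sample.case_ids + sample.control_ids)

    models: list[FittedModel] = []
    accuracies: list[float] = []
    for o in range(plan.n_outer):
        test_rows = np.flatnonzero(plan.outer[row_pair] == o)
        train_mask = plan.outer[row_pair] != o
        inner_models = select_lambda(x, y, plan.inner[o], cfg, row_pair)
        for mod in inner_models:
            mod.outer_fold = o
            mod.train_ids = tuple(
                ids[train_mask & (plan.inner[o][row_pair] != mod.inner_fold)]
            )
            xt = apply_znorm(x[test_rows], mod._znorm)
            accuracies.append(mod.accuracy(xt, y[test_rows]))
            models.append(mod)
    return CVResult(models=models, accuracies=np.array(accuracies), plan=plan)
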