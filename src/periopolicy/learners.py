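"""Super learner: convex stacking of candidate prediction algorithms.

Used for every nuisance model (treatment/density-ratio classifiers,
censoring models, sequential outcome regressions).  Candidates are a
ridge-regularised GLM (the Gaussian-prior MAP counterpart of a Bayesian
GLM), an L1-penalised GLM, a random forest, and -- for discrete designs --
an exact conditional-mean lookup table.  Weights are chosen by minimising
V-fold cross-validated squared-error risk over the probability simplex, so
the ensemble's CV risk never exceeds the best single candidate's.

Rows are canonicalised internally (lexicographic sort over features and
label) before fold assignment and fitting, which makes fitted weights
invariant to the order in which observations are supplied.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.preprocessing import StandardScaler

FAMILIES = ("ridge", "lasso", "random_forest", "mean_table")
TASKS = ("binary", "continuous")

_BINARY_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass(frozen=True)
class LearnerSpec:
    """One candidate algorithm.

    ``penalty_grid`` lists inverse-regularisation strengths (``C`` for
    classifiers, ``1/alpha``-like for regressors); the grid point with the
    lowest CV risk is kept.  Tree hyperparameters apply to random forests.
    """

    id: str
    family: str
    penalty_grid: tuple[float, ...] = (0.01, 1.0, 100.0)
    n_estimators: int = 200
    max_depth: int | None = None
    min_samples_leaf: int = 25

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.family in ("ridge", "lasso") and not self.penalty_grid:
            raise ValueError(f"{self.id}: empty penalty grid")
        if self.family == "random_forest" and self.n_estimators < 1:
            raise ValueError(f"{self.id}: n_estimators must be positive")


def default_learners() -> list[LearnerSpec]:
    """The ensemble used by default: Bayesian-style ridge GLM, lasso, forest."""
    return [
        LearnerSpec("bayes_glm", "ridge"),
        LearnerSpec("lasso", "lasso"),
        LearnerSpec("random_forest", "random_forest"),
    ]


def glm_learners(penalty: float = 1.0) -> list[LearnerSpec]:
    """A single ridge GLM at a fixed mild penalty (fast; used at desk scale).

    The mild ridge keeps the density-ratio classifier's odds stable when
    stacked records are nearly separable in small samples."""
    return [LearnerSpec("glm", "ridge", penalty_grid=(penalty,))]


def saturated_learners() -> list[LearnerSpec]:
    """Exact conditional means over discrete feature combinations."""
    return [LearnerSpec("mean_table", "mean_table")]


# -- fitted candidate wrappers ---------------------------------------------


class _ConstantModel:
    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.value)


#: standardized features are winsorised at +-5 SD for the penalised GLMs so a
#: handful of extreme covariate values cannot drive linear extrapolation of
#: nuisance probabilities to the clipping bounds
_Z_CAP = 5.0


class _SklearnModel:
    def __init__(self, scaler, est, task):
        self.scaler, self.est, self.task = scaler, est, task

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = np.clip(self.scaler.transform(X), -_Z_CAP, _Z_CAP) if self.scaler is not None else X
        if self.task == "binary" and hasattr(self.est, "predict_proba"):
            return self.est.predict_proba(Z)[:, 1]
        return np.asarray(self.est.predict(Z), dtype=float)


class _MeanTable:
    """Group means keyed by the exact feature vector; unseen rows fall back
    to the global mean."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.table: dict[bytes, float] = {}
        self.global_mean = float(np.mean(y))
        sums: dict[bytes, list[float]] = {}
        for row, yi in zip(np.ascontiguousarray(X), y):
            key = row.tobytes()
            acc = sums.setdefault(key, [0.0, 0.0])
            acc[0] += yi
            acc[1] += 1.0
        self.table = {k: s / c for k, (s, c) in sums.items()}

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        for i, row in enumerate(np.ascontiguousarray(X)):
            out[i] = self.table.get(row.tobytes(), self.global_mean)
        return out


def _fit_candidate(spec: LearnerSpec, X, y, task, penalty, seed):
    if spec.family == "mean_table":
        return _MeanTable(X, y)
    if spec.family == "random_forest":
        cls = RandomForestClassifier if task == "binary" else RandomForestRegressor
        est = cls(
            n_estimators=spec.n_estimators,
            max_depth=spec.max_depth,
            min_samples_leaf=spec.min_samples_leaf,
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y.astype(int) if task == "binary" else y)
        return _SklearnModel(None, est, task)
    scaler = StandardScaler().fit(X)
    Z = np.clip(scaler.transform(X), -_Z_CAP, _Z_CAP)
    if task == "binary":
        if spec.family == "ridge":
            est = LogisticRegression(C=penalty, l1_ratio=0.0, solver="lbfgs", max_iter=1000)
        else:
            est = LogisticRegression(
                C=penalty, l1_ratio=1.0, solver="liblinear", max_iter=1000, random_state=0
            )
        est.fit(Z, y.astype(int))
    else:
        if spec.family == "ridge":
            est = Ridge(alpha=1.0 / penalty)
        else:
            est = Lasso(alpha=max(1.0 / penalty, 1e-6) * 0.01, max_iter=5000)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            est.fit(Z, y)
    return _SklearnModel(scaler, est, task)


def _clip(pred: np.ndarray, task: str) -> np.ndarray:
    if task == "binary":
        return np.clip(pred, *_BINARY_CLIP)
    # continuous targets (sequential pseudo-outcomes) are left unbounded:
    # truncating them would bias the ratio-weighted residual terms
    return pred


# -- ensemble --------------------------------------------------------------


@dataclass
class EnsembleModel:
    specs: list[LearnerSpec]
    models: list[object]
    weights: np.ndarray
    cv_risks: np.ndarray
    ensemble_cv_risk: float
    task: str
    n_features: int
    fold_ids: np.ndarray | None
    seed: int
    warnings: list[str] = field(default_factory=list)

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else 'wrong'} columns, "
                f"model was fitted with {self.n_features}"
            )
        preds = np.column_stack([m.predict(X) for m in self.models])
        return _clip(preds @ self.weights, self.task)


def _simplex_weights(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    m = Z.shape[1]
    if m == 1:
        return np.ones(1)

    def risk(w):
        r = Z @ w - y
        return float(r @ r) / len(y)

    def grad(w):
        return 2.0 * Z.T @ (Z @ w - y) / len(y)

    cons = ({"type": "eq", "fun": lambda w: w.sum() - 1.0, "jac": lambda w: np.ones(m)},)
    res = minimize(
        risk,
        np.full(m, 1.0 / m),
        jac=grad,
        bounds=[(0.0, 1.0)] * m,
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum() if w.sum() > 0 else np.full(m, 1.0 / m)
    # simplex vertices are feasible: never do worse than the best candidate
    cand = np.mean((Z - y[:, None]) ** 2, axis=0)
    if risk(w) > cand.min() + 1e-12:
        w = np.zeros(m)
        w[int(np.argmin(cand))] = 1.0
    return w


def fit_superlearner(
    features,
    labels,
    task: str = "binary",
    n_folds: int = 10,
    learner_set: list[LearnerSpec] | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Fit the convex stack.

    Cross-validated predictions are computed per candidate (choosing each
    penalised family's grid point by the same folds), weights minimise CV
    squared error over the simplex, and candidates are refit on all data.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    specs = list(learner_set) if learner_set is not None else default_learners()
    if not specs:
        raise ValueError("at least one learner is required")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-d and aligned with labels")
    n, p = X.shape
    if n < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} rows for {n_folds}-fold CV, got {n}")
    notes: list[str] = []

    # degenerate labels -> constant model
    if np.all(y == y[0]):
        notes.append(f"degenerate labels (constant {y[0]!r}); returning constant model")
        return EnsembleModel(
            specs[:1],
            [_ConstantModel(y[0])],
            np.ones(1),
            np.zeros(1),
            0.0,
            task,
            p,
            None,
            seed,
            notes,
        )

    # canonical row order: invariance to input permutation
    order = np.lexsort(tuple(X.T) + (y,))
    Xs, ys = X[order], y[order]
    rng = np.random.default_rng(seed)
    fold_ids = rng.permutation(n) % n_folds

    single = len(specs) == 1 and (
        specs[0].family in ("mean_table", "random_forest") or len(specs[0].penalty_grid) == 1
    )
    if single:
        pen = specs[0].penalty_grid[0] if specs[0].penalty_grid else 1.0
        model = _fit_candidate(specs[0], Xs, ys, task, pen, seed)
        return EnsembleModel(
            specs, [model], np.ones(1), np.full(1, np.nan), np.nan, task, p, fold_ids, seed, notes
        )

    cv_preds = np.zeros((n, len(specs)))
    chosen_penalty: list[float] = []
    for j, spec in enumerate(specs):
        grid = spec.penalty_grid if spec.family in ("ridge", "lasso") else (1.0,)
        best_risk, best_pred, best_pen = np.inf, None, grid[0]
        for pen in grid:
            pred = np.zeros(n)
            for v in range(n_folds):
                tr, ev = fold_ids != v, fold_ids == v
                if len(np.unique(ys[tr])) < 2 and task == "binary":
                    pred[ev] = ys[tr].mean()
                    continue
                m = _fit_candidate(spec, Xs[tr], ys[tr], task, pen, seed + 7 * v)
                pred[ev] = _clip(m.predict(Xs[ev]), task)
            risk = float(np.mean((pred - ys) ** 2))
            if risk < best_risk:
                best_risk, best_pred, best_pen = risk, pred, pen
        cv_preds[:, j] = best_pred
        chosen_penalty.append(best_pen)

    w = _simplex_weights(cv_preds, ys)
    cv_risks = np.mean((cv_preds - ys[:, None]) ** 2, axis=0)
    ens_risk = float(np.mean((cv_preds @ w - ys) ** 2))
    models = [
        _fit_candidate(spec, Xs, ys, task, pen, seed)
        for spec, pen in zip(specs, chosen_penalty)
    ]
    return EnsembleModel(specs, models, w, cv_risks, ens_risk, task, p, fold_ids, seed, notes)


def predict(model: EnsembleModel, features) -> np.ndarray:
    """Convex combination of candidate predictions (clipped per task)."""
    return model.predict(features)
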