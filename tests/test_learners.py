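"""Super-learner stacking: weights, risks, determinism, degeneracy."""

import numpy as np
import pytest

from periopolicy.learners import (
    EnsembleModel,
    LearnerSpec,
    _ConstantModel,
    fit_superlearner,
    predict,
)


def _sim_binary(seed, n=500, p=8):
    r = np.random.default_rng(seed)
    X = r.standard_normal((n, p))
    logit = 1.5 * X[:, 0] - 1.0 * X[:, 1]
    y = (r.random(n) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
    return X, y


def test_single_learner_gets_weight_one():
    X, y = _sim_binary(0)
    m = fit_superlearner(X, y, "binary", 5, [LearnerSpec("glm", "ridge", penalty_grid=(1.0,))], seed=0)
    assert m.weights.tolist() == [1.0]


def test_weights_on_simplex_and_ensemble_risk_bound():
    X, y = _sim_binary(1)
    specs = [
        LearnerSpec("ridge", "ridge", penalty_grid=(0.1, 1.0)),
        LearnerSpec("lasso", "lasso", penalty_grid=(1.0,)),
        LearnerSpec("forest", "random_forest", n_estimators=50),
    ]
    m = fit_superlearner(X, y, "binary", 4, specs, seed=2)
    assert m.weights.min() >= 0
    assert m.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert m.ensemble_cv_risk <= m.cv_risks.min() + 1e-9


def test_lasso_dominates_on_sparse_truth():
    """On a sparse linear-logit truth the L1 candidate should carry the
    largest weight in the clear majority of replicates."""
    wins = 0
    R = 20
    for rep in range(R):
        r = np.random.default_rng(100 + rep)
        X = r.standard_normal((500, 20))
        logit = 2.0 * X[:, 0] - 1.5 * X[:, 1]
        y = (r.random(500) < 1.0 / (1.0 + np.exp(-logit))).astype(float)
        specs = [
            LearnerSpec("ridge", "ridge", penalty_grid=(0.1,)),
            LearnerSpec("lasso", "lasso", penalty_grid=(1.0,)),
        ]
        m = fit_superlearner(X, y, "binary", 5, specs, seed=rep)
        if m.weights[1] >= m.weights[0]:
            wins += 1
    assert wins >= int(0.8 * R)


def test_degenerate_single_class_returns_constant_with_note():
    X = np.random.default_rng(3).standard_normal((60, 4))
    y = np.ones(60)
    m = fit_superlearner(X, y, "binary", 5, None, seed=0)
    assert m.warnings and "degenerate" in m.warnings[0]
    assert np.allclose(predict(m, X), 1.0 - 1e-6)  # binary clip


def test_convex_combination_hand_case():
    m = EnsembleModel(
        specs=[LearnerSpec("a", "ridge"), LearnerSpec("b", "ridge")],
        models=[_ConstantModel(0.2), _ConstantModel(0.6)],
        weights=np.array([0.5, 0.5]),
        cv_risks=np.zeros(2),
        ensemble_cv_risk=0.0,
        task="continuous",
        n_features=3,
        fold_ids=None,
        seed=0,
    )
    out = predict(m, np.zeros((4, 3)))
    assert np.allclose(out, 0.4)


def test_weight_one_equals_first_candidate():
    X, y = _sim_binary(4)
    specs = [
        LearnerSpec("ridge", "ridge", penalty_grid=(1.0,)),
        LearnerSpec("lasso", "lasso", penalty_grid=(1.0,)),
    ]
    m = fit_superlearner(X, y, "binary", 4, specs, seed=1)
    m.weights = np.array([1.0, 0.0])
    single = m.models[0].predict(X)
    assert np.allclose(predict(m, X), np.clip(single, 1e-6, 1 - 1e-6))


def test_permuted_rows_give_identical_weights():
    X, y = _sim_binary(5, n=300, p=5)
    specs = [
        LearnerSpec("ridge", "ridge", penalty_grid=(1.0,)),
        LearnerSpec("lasso", "lasso", penalty_grid=(1.0,)),
    ]
    m1 = fit_superlearner(X, y, "binary", 4, specs, seed=3)
    perm = np.random.default_rng(9).permutation(len(y))
    m2 = fit_superlearner(X[perm], y[perm], "binary", 4, specs, seed=3)
    assert np.array_equal(m1.weights, m2.weights)


def test_feature_mismatch_rejected():
    X, y = _sim_binary(6)
    m = fit_superlearner(X, y, "binary", 4, [LearnerSpec("glm", "ridge", penalty_grid=(1.0,))], seed=0)
    with pytest.raises(ValueError, match="columns"):
        predict(m, X[:, :3])


def test_too_few_rows_rejected():
    X, y = _sim_binary(7, n=12)
    with pytest.raises(ValueError, match="at least"):
        fit_superlearner(X, y, "binary", 10, None, seed=0)


def test_mean_table_is_exact_on_discrete_design():
    r = np.random.default_rng(8)
    X = r.integers(0, 2, size=(400, 3)).astype(float)
    y = X[:, 0] * 0.5 + 0.1
    m = fit_superlearner(X, y, "continuous", 5, [LearnerSpec("t", "mean_table")], seed=0)
    assert np.allclose(predict(m, X), y)
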