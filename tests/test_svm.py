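"""SVM dual solution and Platt calibration, checked against a scipy QP oracle."""

import numpy as np
import pytest
from scipy.optimize import minimize

import diabfuse as df
from diabfuse.svm import (
    KernelSpec,
    PlattCalibration,
    SVMModel,
    decision_value,
    decision_values,
    fit_platt,
    kernel_eval,
    kernel_matrix,
    svm_posterior,
    train_svm,
)


def qp_oracle_dual_objective(X, labels, C, spec):
    """Brute-force dual solve with SLSQP, independent of the libsvm path."""
    y = np.where(np.asarray(labels) == 1, 1.0, -1.0)
    K = kernel_matrix(spec, X, X)
    Q = np.outer(y, y) * K

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    n = len(y)
    res = minimize(
        neg_dual,
        x0=np.full(n, min(C, 1.0) / 2),
        jac=lambda a: -(np.ones(n) - Q @ a),
        bounds=[(0.0, C)] * n,
        constraints={"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y},
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    assert res.success
    return -res.fun


@pytest.mark.parametrize(
    "spec, x, z, expected",
    [
        (KernelSpec("rbf", gamma=0.7), [1.0, 2.0], [1.0, 2.0], 1.0),
        (KernelSpec("linear"), [1.0, 0.0], [0.0, 1.0], 0.0),
        (KernelSpec("polynomial", gamma=1.0, r=1.0, d=2), [1.0, 0.0], [1.0, 0.0], 4.0),
        (KernelSpec("sigmoid", gamma=1.0, r=0.0), [1.0, 0.0], [1.0, 0.0], np.tanh(1.0)),
    ],
)
def test_kernel_eval_formulas(spec, x, z, expected):
    assert kernel_eval(spec, x, z) == pytest.approx(expected)


def test_kernel_dimension_mismatch():
    with pytest.raises(ValueError):
        kernel_eval(KernelSpec("linear"), [1.0], [1.0, 2.0])


def test_max_margin_hand_solution():
    X = np.array([[0.0, 0.0], [2.0, 2.0]])
    labels = np.array([0, 1])
    model = train_svm((X, labels), C=1e6, kernel=KernelSpec("linear"))
    # midpoint lies on the separating hyperplane; training points classified correctly
    assert decision_value(model, [1.0, 1.0]) == pytest.approx(0.0, abs=1e-6)
    assert decision_value(model, X[0]) == pytest.approx(-1.0, abs=1e-4)
    assert decision_value(model, X[1]) == pytest.approx(1.0, abs=1e-4)


def test_xor_with_rbf_kernel():
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    labels = np.array([0, 0, 1, 1])
    model = train_svm((X, labels), C=10.0, kernel=KernelSpec("rbf", gamma=1.0))
    pred = (decision_values(model, X) >= 0).astype(int)
    np.testing.assert_array_equal(pred, labels)


def test_decision_value_hand_cases():
    spec = KernelSpec("linear")
    empty = SVMModel(
        support_vectors=np.empty((0, 2)),
        dual_coefs=np.empty(0),
        bias=0.5,
        kernel=spec,
        C=1.0,
        n_features=2,
    )
    assert decision_value(empty, [3.0, 4.0]) == 0.5
    one_sv = SVMModel(
        support_vectors=np.array([[1.0, 1.0]]),
        dual_coefs=np.array([1.0]),
        bias=0.0,
        kernel=spec,
        C=1.0,
        n_features=2,
    )
    assert decision_value(one_sv, [1.0, 1.0]) == pytest.approx(2.0)


def test_dual_feasibility_and_determinism(blobs):
    X, labels = blobs(n=80, sep=2.0, seed=3)
    model = train_svm((X, labels), C=5.0)
    model.check_dual_feasibility(tol=1e-3)
    # duplicate query of a training point reproduces its decision value
    assert decision_value(model, X[0]) == pytest.approx(
        decision_values(model, X[:1])[0], abs=1e-9
    )


def test_row_order_invariance(blobs):
    X, labels = blobs(n=60, sep=2.0, seed=5)
    m1 = train_svm((X, labels), C=1.0)
    perm = np.random.default_rng(0).permutation(len(labels))
    m2 = train_svm((X[perm], labels[perm]), C=1.0)
    q = np.random.default_rng(1).normal(size=(20, 2))
    np.testing.assert_allclose(
        decision_values(m1, q), decision_values(m2, q), atol=1e-6
    )


@pytest.mark.parametrize("kind", ["linear", "rbf"])
def test_dual_objective_matches_qp_oracle(kind, blobs):
    X, labels = blobs(n=12, sep=1.5, seed=11)
    spec = KernelSpec(kind, gamma=0.5 if kind == "rbf" else None)
    C = 2.0
    model = train_svm((X, labels), C=C, kernel=spec)
    oracle = qp_oracle_dual_objective(X, labels, C, spec)
    assert model.dual_objective() == pytest.approx(oracle, abs=1e-3)


def test_single_class_and_bad_C_rejected(blobs):
    X, labels = blobs(n=20, seed=0)
    with pytest.raises(ValueError):
        train_svm((X, np.zeros_like(labels)), C=1.0)
    with pytest.raises(ValueError):
        train_svm((X, labels), C=-1.0)


def test_platt_monotone_and_separating():
    f = np.array([-2.0, -1.5, -1.0, 1.0, 1.5, 2.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    cal = fit_platt(f, labels)
    post = cal.posterior(f)
    assert np.all(np.diff(post) > 0)
    assert cal.posterior(1.0) > 0.5 > cal.posterior(-1.0)


def test_platt_symmetric_balanced_is_half_at_zero():
    f = np.array([-2.0, -1.0, 1.0, 2.0])
    labels = np.array([0, 0, 1, 1])
    cal = fit_platt(f, labels)
    assert cal.posterior(0.0) == pytest.approx(0.5, abs=1e-6)


def test_platt_uninformative_scores_recover_prevalence():
    rng = np.random.default_rng(0)
    f = rng.normal(size=500)
    labels = (rng.random(500) < 0.3).astype(int)  # independent of f
    cal = fit_platt(f, labels)
    post = cal.posterior(np.linspace(-2, 2, 9))
    assert np.all(np.abs(post - labels.mean()) < 0.05)


def test_platt_requires_both_classes():
    with pytest.raises(ValueError):
        fit_platt([0.1, 0.2], [1, 1])


def test_svm_posterior_properties(blobs):
    X, labels = blobs(n=60, sep=2.0, seed=2)
    model = train_svm((X, labels), C=1.0)
    cal = fit_platt(decision_values(model, X), labels)
    f = np.sort(decision_values(model, X))
    post = np.asarray(cal.posterior(f))
    assert np.all((post > 0) & (post < 1))
    assert np.all(np.diff(post) >= 0)
    p = svm_posterior(model, cal, X[0])
    assert p + (1 - p) == pytest.approx(1.0)
    # agrees with the direct sigmoid formula
    fx = decision_value(model, X[0])
    assert p == pytest.approx(1.0 / (1.0 + np.exp(cal.A * fx + cal.B)))


def test_model_json_round_trip(blobs):
    X, labels = blobs(n=30, sep=2.0, seed=9)
    model = train_svm((X, labels), C=1.0)
    back = SVMModel.from_json(model.to_json())
    q = np.random.default_rng(3).normal(size=(5, 2))
    np.testing.assert_allclose(decision_values(back, q), decision_values(model, q))
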