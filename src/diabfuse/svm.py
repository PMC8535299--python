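"""Binary support vector machine with the four standard kernels, plus
Platt-type sigmoid calibration.

The classifier solves the soft-margin dual

    max_a  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t.   0 <= a_i <= C,   sum_i a_i y_i = 0

with labels mapped dataset-1 (diabetic, target class) -> y = +1 and
dataset-0 -> y = -1, and decides by sign(sum_i a_i y_i K(x_i, x) + b).
The quadratic program is delegated to libsvm (via scikit-learn) on a
kernel matrix computed here, so the kernel semantics below are the single
source of truth; the returned model is checked against the dual box and
equality constraints independently of the backend.

Posterior probabilities P(class 1 | x), required by the downstream fusion
layer, come from a two-parameter sigmoid 1/(1 + exp(A f + B)) fit to
decision values f by regularized maximum likelihood (Platt scaling, with
the smoothed targets and damped Newton iteration of Lin, Weng & Keerthi).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .schema import LabeledDataset

__all__ = [
    "KernelSpec",
    "SVMModel",
    "PlattCalibration",
    "kernel_eval",
    "kernel_matrix",
    "train_svm",
    "decision_value",
    "fit_platt",
    "svm_posterior",
    "CalibratedSVM",
]

KERNELS = ("linear", "rbf", "polynomial", "sigmoid")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    gamma is the scale γ (required positive for rbf/polynomial/sigmoid;
    ``None`` means 1/d, resolved at fit time), ``r`` the additive constant of
    the polynomial/sigmoid kernels, ``d`` the polynomial degree.
    """

    kind: str = "rbf"
    gamma: float | None = None
    r: float = 0.0
    d: int = 3

    def __post_init__(self) -> None:
        if self.kind not in KERNELS:
            raise ValueError(f"unknown kernel {self.kind!r}; expected one of {KERNELS}")
        if self.gamma is not None and self.gamma <= 0 and self.kind != "linear":
            raise ValueError("gamma must be positive")
        if self.d < 1:
            raise ValueError("polynomial degree must be >= 1")

    def resolve(self, n_features: int) -> "KernelSpec":
        if self.gamma is None and self.kind != "linear":
            return KernelSpec(self.kind, 1.0 / n_features, self.r, self.d)
        return self


def kernel_eval(spec: KernelSpec, x, z) -> float:
    """K(x, z) for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("kernel arguments must have the same dimension")
    return float(kernel_matrix(spec, x[None, :], z[None, :])[0, 0])


def kernel_matrix(spec: KernelSpec, X, Z) -> np.ndarray:
    """Gram matrix K[i, j] = K(X[i], Z[j])."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if X.shape[1] != Z.shape[1]:
        raise ValueError("kernel arguments must have the same dimension")
    spec = spec.resolve(X.shape[1])
    inner = X @ Z.T
    if spec.kind == "linear":
        return inner
    if spec.kind == "rbf":
        sq = (X**2).sum(1)[:, None] + (Z**2).sum(1)[None, :] - 2.0 * inner
        return np.exp(-spec.gamma * np.maximum(sq, 0.0))
    if spec.kind == "polynomial":
        return (spec.gamma * inner + spec.r) ** spec.d
    return np.tanh(spec.gamma * inner + spec.r)  # sigmoid


@dataclass
class SVMModel:
    """Trained SVM: support vectors, signed dual coefficients a_i*y_i, bias."""

    support_vectors: np.ndarray
    dual_coefs: np.ndarray  # a_i * y_i, one per support vector
    bias: float
    kernel: KernelSpec
    C: float
    n_features: int

    @property
    def alphas(self) -> np.ndarray:
        return np.abs(self.dual_coefs)

    def check_dual_feasibility(self, tol: float = 1e-6) -> None:
        """Assert 0 <= a_i <= C and sum a_i y_i = 0 within tolerance."""
        a = self.alphas
        if (a < -tol).any() or (a > self.C + tol).any():
            raise AssertionError("dual box constraint 0 <= a_i <= C violated")
        if abs(float(self.dual_coefs.sum())) > max(tol, 1e-6 * max(1.0, a.sum())):
            raise AssertionError("dual equality constraint sum a_i y_i = 0 violated")

    def dual_objective(self) -> float:
        """Value of the dual objective at the stored multipliers."""
        a = self.alphas
        y = np.sign(self.dual_coefs)
        K = kernel_matrix(self.kernel, self.support_vectors, self.support_vectors)
        return float(a.sum() - 0.5 * (a * y) @ K @ (a * y))

    def to_json(self) -> str:
        return json.dumps(
            {
                "kernel": {
                    "kind": self.kernel.kind,
                    "gamma": self.kernel.gamma,
                    "r": self.kernel.r,
                    "d": self.kernel.d,
                },
                "C": self.C,
                "n_features": self.n_features,
                "support_vectors": self.support_vectors.tolist(),
                "dual_coefs": self.dual_coefs.tolist(),
                "bias": self.bias,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SVMModel":
        o = json.loads(text)
        return cls(
            support_vectors=np.asarray(o["support_vectors"], dtype=float),
            dual_coefs=np.asarray(o["dual_coefs"], dtype=float),
            bias=float(o["bias"]),
            kernel=KernelSpec(**o["kernel"]),
            C=float(o["C"]),
            n_features=int(o["n_features"]),
        )


def train_svm(
    train: LabeledDataset | tuple[np.ndarray, np.ndarray],
    C: float = 1.0,
    kernel: KernelSpec | None = None,
    tol: float = 1e-6,
) -> SVMModel:
    """Fit the soft-margin SVM on complete, standardized features.

    Accepts either a :class:`LabeledDataset` or an ``(X, labels01)`` pair.
    """
    if isinstance(train, LabeledDataset):
        X, labels = train.values, train.labels
    else:
        X, labels = train
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=int)
    if C <= 0:
        raise ValueError("penalty C must be positive")
    if np.isnan(X).any():
        raise ValueError("training data must be complete (impute first)")
    y = np.where(labels == 1, 1, -1)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    spec = (kernel or KernelSpec()).resolve(X.shape[1])
    gram = kernel_matrix(spec, X, X)
    clf = SVC(C=C, kernel="precomputed", tol=tol, shrinking=False)
    clf.fit(gram, y)

    sv_idx = clf.support_
    model = SVMModel(
        support_vectors=X[sv_idx].copy(),
        dual_coefs=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        kernel=spec,
        C=C,
        n_features=X.shape[1],
    )
    model.check_dual_feasibility(tol=1e-3)
    return model


def decision_value(model: SVMModel, x) -> float:
    """f(x) = sum_i a_i y_i K(x_i, x) + b."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.n_features:
        raise ValueError("query dimension does not match the model")
    if model.support_vectors.size == 0:
        return model.bias
    k = kernel_matrix(model.kernel, model.support_vectors, x[None, :]).ravel()
    return float(model.dual_coefs @ k + model.bias)


def _stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Class-wise round-robin fold indices for internal calibration splits."""
    rng = np.random.default_rng(seed)
    fold = np.empty(labels.shape[0], dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % k
    return fold


def decision_values(model: SVMModel, X) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.support_vectors.size == 0:
        return np.full(X.shape[0], model.bias)
    k = kernel_matrix(model.kernel, model.support_vectors, X)
    return model.dual_coefs @ k + model.bias


@dataclass(frozen=True)
class PlattCalibration:
    """Sigmoid map from decision values to P(class 1 | x): 1/(1+exp(A f + B))."""

    A: float
    B: float

    def posterior(self, f) -> np.ndarray | float:
        z = self.A * np.asarray(f, dtype=float) + self.B
        # numerically safe logistic
        out = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        return float(out) if out.ndim == 0 else out


def fit_platt(decision_vals, labels, max_iter: int = 100) -> PlattCalibration:
    """Fit (A, B) by regularized maximum likelihood with smoothed targets.

    Targets are t+ = (N+ + 1)/(N+ + 2) and t- = 1/(N- + 2); initialization is
    A = 0, B = ln((N- + 1)/(N+ + 1)); optimization is a damped Newton descent
    on the cross-entropy, deterministic given the inputs.
    """
    f = np.asarray(decision_vals, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(f).all():
        raise ValueError("decision values must be finite")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("calibration needs both classes present")

    t = np.where(labels == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    A, B = 0.0, math.log((n_neg + 1.0) / (n_pos + 1.0))
    sigma = 1e-12
    min_step = 1e-10

    def nll(a: float, b: float) -> float:
        z = a * f + b
        # -sum [t*log(p) + (1-t)*log(1-p)] with p = 1/(1+e^z)
        return float(np.sum(t * z + np.logaddexp(0.0, -z)))

    fval = nll(A, B)
    for _ in range(max_iter):
        z = A * f + B
        p = np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))
        d1 = t - p
        d2 = p * (1.0 - p)
        g_a = float(np.dot(f, d1))
        g_b = float(d1.sum())
        if abs(g_a) < 1e-5 and abs(g_b) < 1e-5:
            break
        h11 = float(np.dot(f * f, d2)) + sigma
        h22 = float(d2.sum()) + sigma
        h21 = float(np.dot(f, d2))
        det = h11 * h22 - h21 * h21
        dA = -(h22 * g_a - h21 * g_b) / det
        dB = -(-h21 * g_a + h11 * g_b) / det
        gd = g_a * dA + g_b * dB
        step = 1.0
        while step >= min_step:
            nA, nB = A + step * dA, B + step * dB
            nf = nll(nA, nB)
            if nf < fval + 1e-4 * step * gd:
                A, B, fval = nA, nB, nf
                break
            step /= 2.0
        else:
            break
    return PlattCalibration(A=A, B=B)


def svm_posterior(model: SVMModel, cal: PlattCalibration, x) -> float:
    """Calibrated posterior P(class 1 | x), strictly monotone in the decision value."""
    return float(cal.posterior(decision_value(model, x)))


class CalibratedSVM:
    """SVM + Platt sigmoid bundled behind the fusion-member interface.

    Calibration uses out-of-fold decision values (``cal_folds``-fold,
    stratified, fixed internal seed) rather than the training decision
    values of the final model, which are biased toward overconfidence;
    with ``cal_folds=1`` the training values are used directly.
    """

    def __init__(self, C: float = 1.0, kernel: KernelSpec | None = None, cal_folds: int = 3):
        self.C = C
        self.kernel = kernel or KernelSpec()
        self.cal_folds = cal_folds
        self.model: SVMModel | None = None
        self.calibration: PlattCalibration | None = None

    def fit(self, train: LabeledDataset) -> "CalibratedSVM":
        self.model = train_svm(train, C=self.C, kernel=self.kernel)
        X, labels = train.values, train.labels
        counts = np.bincount(labels, minlength=2)
        if self.cal_folds >= 2 and counts.min() >= self.cal_folds:
            f = np.empty(len(labels))
            fold = _stratified_folds(labels, self.cal_folds)
            for k in range(self.cal_folds):
                te = fold == k
                sub = train.subset(np.flatnonzero(~te))
                m = train_svm(sub, C=self.C, kernel=self.kernel)
                f[te] = decision_values(m, X[te])
        else:
            f = decision_values(self.model, X)
        self.calibration = fit_platt(f, labels)
        return self

    def _require_fit(self) -> None:
        if self.model is None or self.calibration is None:
            raise RuntimeError("CalibratedSVM is not fitted")

    def posterior_target(self, x) -> float:
        self._require_fit()
        return svm_posterior(self.model, self.calibration, x)

    def posterior_target_batch(self, X) -> np.ndarray:
        self._require_fit()
        return np.asarray(self.calibration.posterior(decision_values(self.model, X)))

    def predict(self, X) -> np.ndarray:
        self._require_fit()
        return (decision_values(self.model, X) >= 0).astype(int)
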