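"""Single-hidden-layer sigmoid network trained by classic per-sample backprop.

Architecture: d inputs -> h logistic-sigmoid hidden units -> K logistic
outputs (K = 1 by default; the single output is read as P(class 1 | x)).
Training minimizes the half sum-of-squares error E = 1/2 Σ_k (τ_k - o_k)²
by stochastic gradient descent: for each sample, the output delta is
ξ_k = (τ_k - o_k)·o_k(1 - o_k), the hidden delta ξ_j = (Σ_k ξ_k ν_jk)·
h_j(1 - h_j), and weights move by +λF·ξ·activation — i.e. gradient descent
on E (the deltas are the negative error gradients; the analytic gradients
are checked against central finite differences in the test suite).

Everything is implemented directly on numpy arrays: weight initialization,
feedforward, backpropagation, weight update, and the epoch loop with a
seed-shuffled visiting order, so training is bit-reproducible given
(data, config).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .schema import LabeledDataset

__all__ = [
    "ANNConfig",
    "ANNModel",
    "Gradients",
    "forward",
    "sse_error",
    "backprop_deltas",
    "update_weights",
    "train_ann",
    "ann_posterior",
    "ANNClassifier",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass(frozen=True)
class ANNConfig:
    n_hidden: int = 8
    learning_rate: float = 0.5  # λF
    epochs: int = 200
    init_range: float = 0.5
    seed: int = 0
    tolerance: float = 0.0  # early stop when epoch-SSE improvement < tolerance

    def __post_init__(self) -> None:
        if self.n_hidden < 1 or self.epochs < 1:
            raise ValueError("n_hidden and epochs must be positive")
        if self.learning_rate <= 0 or self.init_range <= 0:
            raise ValueError("learning_rate and init_range must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass
class ANNModel:
    """Weights of the d-h-K network; all activations are logistic sigmoids."""

    w_in: np.ndarray  # (d, h) input->hidden weights w_ij
    b_hidden: np.ndarray  # (h,)
    w_out: np.ndarray  # (h, K) hidden->output weights ν_jk
    b_out: np.ndarray  # (K,)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.w_in.shape[0], self.w_in.shape[1], self.w_out.shape[1]

    def copy(self) -> "ANNModel":
        return ANNModel(
            self.w_in.copy(), self.b_hidden.copy(), self.w_out.copy(), self.b_out.copy()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "w_in": self.w_in.tolist(),
                "b_hidden": self.b_hidden.tolist(),
                "w_out": self.w_out.tolist(),
                "b_out": self.b_out.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        o = json.loads(text)
        return cls(
            w_in=np.asarray(o["w_in"], dtype=float),
            b_hidden=np.asarray(o["b_hidden"], dtype=float),
            w_out=np.asarray(o["w_out"], dtype=float),
            b_out=np.asarray(o["b_out"], dtype=float),
        )


def forward(model: ANNModel, r) -> tuple[np.ndarray, np.ndarray]:
    """One feedforward pass: returns (hidden activations, outputs)."""
    r = np.asarray(r, dtype=float)
    if r.shape != (model.w_in.shape[0],):
        raise ValueError("input dimension does not match the network")
    hidden = _sigmoid(model.b_hidden + r @ model.w_in)
    out = _sigmoid(model.b_out + hidden @ model.w_out)
    return hidden, out


def sse_error(outputs, targets) -> float:
    """Half sum-of-squares error E = 1/2 Σ (τ_k - o_k)²."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError("outputs and targets must have the same length")
    return float(0.5 * np.sum((targets - outputs) ** 2))


@dataclass
class Gradients:
    """Raw weight increments (negative error gradients, ε = 1)."""

    d_w_in: np.ndarray
    d_b_hidden: np.ndarray
    d_w_out: np.ndarray
    d_b_out: np.ndarray


def backprop_deltas(model: ANNModel, r, tau) -> Gradients:
    """Backpropagated increments for one sample.

    The returned arrays are the increments Δ to be *added* scaled by the
    learning rate; they equal -∂E/∂w for every weight.
    """
    r = np.asarray(r, dtype=float)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    hidden, out = forward(model, r)
    xi_out = (tau - out) * out * (1.0 - out)  # ξ_k
    xi_hidden = (model.w_out @ xi_out) * hidden * (1.0 - hidden)  # ξ_j
    return Gradients(
        d_w_in=np.outer(r, xi_hidden),
        d_b_hidden=xi_hidden,
        d_w_out=np.outer(hidden, xi_out),
        d_b_out=xi_out,
    )


def update_weights(model: ANNModel, grads: Gradients, learning_rate: float) -> ANNModel:
    """w+ = w + λF·Δw (and likewise for ν and the biases)."""
    return ANNModel(
        w_in=model.w_in + learning_rate * grads.d_w_in,
        b_hidden=model.b_hidden + learning_rate * grads.d_b_hidden,
        w_out=model.w_out + learning_rate * grads.d_w_out,
        b_out=model.b_out + learning_rate * grads.d_b_out,
    )


def init_model(n_features: int, config: ANNConfig, n_outputs: int = 1) -> ANNModel:
    rng = np.random.default_rng(config.seed)
    u = config.init_range
    return ANNModel(
        w_in=rng.uniform(-u, u, size=(n_features, config.n_hidden)),
        b_hidden=rng.uniform(-u, u, size=config.n_hidden),
        w_out=rng.uniform(-u, u, size=(config.n_hidden, n_outputs)),
        b_out=rng.uniform(-u, u, size=n_outputs),
    )


def train_ann(
    train: LabeledDataset | tuple[np.ndarray, np.ndarray],
    config: ANNConfig | None = None,
    log: list | None = None,
) -> ANNModel:
    """Stochastic backprop training, deterministic given (data, config).

    Samples are visited in a freshly shuffled order each epoch; training
    stops after ``config.epochs`` epochs or when the epoch SSE improves by
    less than ``config.tolerance``. An optional ``log`` list collects
    (epoch, SSE) pairs.
    """
    import warnings

    config = config or ANNConfig()
    if isinstance(train, LabeledDataset):
        X, labels = train.values, train.labels
    else:
        X, labels = train
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels, dtype=int)
    if np.isnan(X).any():
        raise ValueError("training data must be complete (impute first)")
    if len(np.unique(labels)) < 2:
        warnings.warn("training data contains a single class; proceeding anyway")

    n, d = X.shape
    model = init_model(d, config)
    rng = np.random.default_rng(config.seed)
    targets = labels.astype(float)

    w_in, b_hidden = model.w_in, model.b_hidden
    w_out, b_out = model.w_out.ravel(), float(model.b_out[0])
    lr = config.learning_rate

    prev_sse = np.inf
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sse = 0.0
        for i in order:
            r = X[i]
            hidden = _sigmoid(b_hidden + r @ w_in)
            z = b_out + hidden @ w_out
            o = 1.0 / (1.0 + np.exp(-z)) if z >= 0 else np.exp(z) / (1.0 + np.exp(z))
            err = targets[i] - o
            sse += 0.5 * err * err
            xi_out = err * o * (1.0 - o)
            xi_hidden = (w_out * xi_out) * hidden * (1.0 - hidden)
            w_out += lr * xi_out * hidden
            b_out += lr * xi_out
            w_in += lr * np.outer(r, xi_hidden)
            b_hidden += lr * xi_hidden
        if log is not None:
            log.append((epoch, sse))
        if abs(prev_sse - sse) < config.tolerance:
            break
        prev_sse = sse

    return ANNModel(
        w_in=w_in, b_hidden=b_hidden, w_out=w_out.reshape(-1, 1), b_out=np.array([b_out])
    )


def ann_posterior(model: ANNModel, x) -> float:
    """The network output read as P(class 1 | x)."""
    _, out = forward(model, x)
    return float(out[0])


class ANNClassifier:
    """Trained network behind the fusion-member interface."""

    def __init__(self, config: ANNConfig | None = None):
        self.config = config or ANNConfig()
        self.model: ANNModel | None = None

    def fit(self, train: LabeledDataset) -> "ANNClassifier":
        self.model = train_ann(train, self.config)
        return self

    def _require_fit(self) -> None:
        if self.model is None:
            raise RuntimeError("ANNClassifier is not fitted")

    def posterior_target(self, x) -> float:
        self._require_fit()
        return ann_posterior(self.model, x)

    def posterior_target_batch(self, X) -> np.ndarray:
        self._require_fit()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        hidden = _sigmoid(self.model.b_hidden + X @ self.model.w_in)
        out = _sigmoid(self.model.b_out + hidden @ self.model.w_out)
        return out[:, 0]

    def predict(self, X) -> np.ndarray:
        return (self.posterior_target_batch(X) >= 0.5).astype(int)
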