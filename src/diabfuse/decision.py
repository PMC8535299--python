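"""Posterior-probability fusion of base classifiers and the decision layer.

Each of the L calibrated members i reports a posterior P_i(φt|x) for the
target class φt (diabetic, label 1); the complement class φo (non-diabetic,
label 0) is the "outlier". The combining rules are

    mean:    μ(φt|x) = (1/L) Σ_i P_i(φt|x)
    min/max: extrema over members
    product: Π_i P_i(φt|x)

Two decision modes are supported:

* ``mean_posterior`` — declare the target class iff μ(φt|x) >= μ(φo|x)
  (for the mean rule over two classes this is mean posterior >= 1/2);
* ``density_threshold`` — compare the averaged class-conditional density
  Yavg(x) = (1/L) Σ_i P_i(x|φt) against the threshold
  θ̄ = (P(φo)/P(φt)) · mean(θ_i), declaring x an outlier when Yavg(x) < θ̄.
  P_i(x|φt) is recovered from the posterior as P_i(φt|x)·P(x)/P(φt); the
  common density P(x) is unknowable and dropped, so Yavg here is a proxy
  defined up to that positive factor, which the tunable θ̄ absorbs.

Equality at either boundary goes to the target class: the outlier
criterion is the strict inequality.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .evaluation import confusion
from .schema import LabeledDataset

__all__ = [
    "ClassPriors",
    "FusionModel",
    "FusionDecision",
    "combine_rule",
    "fusion_threshold",
    "average_density",
    "classify",
    "sweep_threshold",
]

RULES = ("mean", "min", "max", "product")
MODES = ("mean_posterior", "density_threshold")
_CLIP = 1e-12


class FusionMember(Protocol):
    def posterior_target(self, x) -> float: ...


@dataclass(frozen=True)
class ClassPriors:
    """P(φt) and P(φo); must be a proper two-class distribution."""

    p_target: float
    p_outlier: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_target < 1.0 and 0.0 < self.p_outlier < 1.0):
            raise ValueError("priors must lie strictly in (0, 1)")
        if abs(self.p_target + self.p_outlier - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    @classmethod
    def from_labels(cls, labels) -> "ClassPriors":
        labels = np.asarray(labels, dtype=int)
        p1 = float((labels == 1).mean())
        return cls(p_target=p1, p_outlier=1.0 - p1)


@dataclass(frozen=True)
class FusionDecision:
    mu_target: float
    mu_outlier: float
    y_avg: float
    threshold: float
    label: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu_t": self.mu_target,
                "mu_o": self.mu_outlier,
                "y_avg": self.y_avg,
                "threshold": self.threshold,
                "label": self.label,
            }
        )


def combine_rule(posteriors: Sequence[float], rule: str = "mean") -> float:
    """Combine member posteriors by one of the four standard rules."""
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    p = np.asarray(posteriors, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one posterior")
    if rule == "mean":
        return float(p.mean())
    if rule == "min":
        return float(p.min())
    if rule == "max":
        return float(p.max())
    return float(p.prod())


def fusion_threshold(priors: ClassPriors, theta_i: Sequence[float]) -> float:
    """θ̄ = (P(φo)/P(φt)) · mean(θ_i)."""
    theta = np.asarray(theta_i, dtype=float)
    if theta.size == 0 or (theta <= 0).any():
        raise ValueError("per-member density levels θ_i must be positive")
    return priors.p_outlier / priors.p_target * float(theta.mean())


@dataclass
class FusionModel:
    """L calibrated members plus priors, density levels, rule and mode."""

    members: list
    priors: ClassPriors
    theta_i: tuple[float, ...] | None = None
    rule: str = "mean"
    mode: str = "mean_posterior"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("need at least one member classifier")
        if self.theta_i is None:
            self.theta_i = tuple(1.0 for _ in self.members)
        if len(self.theta_i) != len(self.members):
            raise ValueError("one θ_i per member required")
        if self.rule not in RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def threshold(self) -> float:
        return fusion_threshold(self.priors, self.theta_i)

    def member_posteriors(self, x) -> np.ndarray:
        """P_i(φt|x) per member, clipped away from exact 0/1."""
        p = np.array([m.posterior_target(x) for m in self.members], dtype=float)
        return np.clip(p, _CLIP, 1.0 - _CLIP)

    def member_posterior_matrix(self, X) -> np.ndarray:
        """(n, L) posterior matrix using members' batch path where available."""
        cols = []
        for m in self.members:
            if hasattr(m, "posterior_target_batch"):
                cols.append(np.asarray(m.posterior_target_batch(X), dtype=float))
            else:
                cols.append(np.array([m.posterior_target(x) for x in np.atleast_2d(X)]))
        return np.clip(np.column_stack(cols), _CLIP, 1.0 - _CLIP)


def member_posteriors(fm: FusionModel, x) -> np.ndarray:
    return fm.member_posteriors(x)


def average_density(fm: FusionModel, x) -> float:
    """Yavg proxy: mean member posterior divided by the target prior."""
    p = fm.member_posteriors(x)
    return float(p.mean() / fm.priors.p_target)


def classify(fm: FusionModel, x, threshold: float | None = None) -> FusionDecision:
    """Fuse member posteriors and decide target (1) vs outlier (0).

    ``threshold`` overrides the model's θ̄ in density_threshold mode.
    """
    p = fm.member_posteriors(x)
    mu_t = combine_rule(p, fm.rule)
    mu_o = combine_rule(1.0 - p, fm.rule)
    y_avg = float(p.mean() / fm.priors.p_target)
    theta_bar = fm.threshold if threshold is None else float(threshold)
    if fm.mode == "mean_posterior":
        label = 0 if mu_t < mu_o else 1
    else:
        label = 0 if y_avg < theta_bar else 1
    return FusionDecision(
        mu_target=mu_t, mu_outlier=mu_o, y_avg=y_avg, threshold=theta_bar, label=label
    )


def predict(fm: FusionModel, X, threshold: float | None = None) -> np.ndarray:
    """Vectorized labels for an (n, d) matrix under the model's mode."""
    P = fm.member_posterior_matrix(X)
    if fm.rule == "mean":
        mu_t = P.mean(axis=1)
        mu_o = 1.0 - mu_t
    else:
        mu_t = np.array([combine_rule(row, fm.rule) for row in P])
        mu_o = np.array([combine_rule(1.0 - row, fm.rule) for row in P])
    if fm.mode == "mean_posterior":
        return (mu_t >= mu_o).astype(int)
    theta_bar = fm.threshold if threshold is None else float(threshold)
    y_avg = P.mean(axis=1) / fm.priors.p_target
    return (y_avg >= theta_bar).astype(int)


def sweep_threshold(fm: FusionModel, ds: LabeledDataset, grid: Sequence[float]) -> pd.DataFrame:
    """FPR/FNR trade-off table over a grid of θ̄ values (density mode).

    Lowering θ̄ admits more records into the target class, so the
    false-negative rate can only fall and the false-positive rate only rise.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    P = fm.member_posterior_matrix(ds.values)
    y_avg = P.mean(axis=1) / fm.priors.p_target
    rows = []
    for theta_bar in grid:
        pred = (y_avg >= theta_bar).astype(int)
        cm = confusion(ds.labels, pred)
        fpr = cm.fp / (cm.fp + cm.tn) if (cm.fp + cm.tn) else math.nan
        fnr = cm.fn / (cm.fn + cm.tp) if (cm.fn + cm.tp) else math.nan
        rows.append({"threshold": theta_bar, "fpr": fpr, "fnr": fnr})
    return pd.DataFrame(rows)
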