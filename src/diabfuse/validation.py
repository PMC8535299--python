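"""Stratified K-fold splitting, inner grid search, and nested cross-validation.

The outer loop (default K = 5) estimates generalization performance; inside
each outer training set an inner stratified loop (default 3 folds) selects
hyperparameters by grid search on accuracy. All preprocessing (zero-to-missing
marking is assumed done upstream; mean imputation and standardization) is fit
on the respective training portion only, so no held-out record ever
contributes to imputation means, standardization statistics, classifier
training, or fusion priors.

Fold aggregates follow M = mean(P_n) ± sample SD (K-1 denominator); because
published tables sometimes pool predictions instead, the report carries both
the mean-over-folds aggregate and pooled-over-folds metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from ._util import derive_seed
from .ann import ANNClassifier, ANNConfig
from .decision import ClassPriors, FusionModel, predict as fusion_predict
from .evaluation import MetricsReport, confusion, metrics
from .preprocessing import (
    fit_imputer,
    fit_standardizer,
    impute,
    standardize,
)
from .schema import LabeledDataset
from .svm import CalibratedSVM, KernelSpec

__all__ = [
    "FoldAssignment",
    "GridSpec",
    "CVReport",
    "stratified_kfold",
    "grid_search",
    "nested_cv",
    "aggregate",
]

CLASSIFIERS = ("svm", "ann", "fusion")


@dataclass(frozen=True)
class FoldAssignment:
    fold_index: np.ndarray
    K: int
    seed: int

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == k)

    def train_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != k)


def stratified_kfold(labels, K: int, seed: int = 0) -> FoldAssignment:
    """Class-wise shuffled round-robin assignment into K folds.

    Keeps each fold's class-1 share within 1/(fold size) of the overall
    share; deterministic given the seed.
    """
    labels = np.asarray(labels, dtype=int)
    if K < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    fold = np.empty(labels.shape[0], dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size < K:
            raise ValueError(f"class {cls} has fewer members ({idx.size}) than folds ({K})")
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % K
    return FoldAssignment(fold_index=fold, K=K, seed=seed)


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter candidates: (C, γ) for the SVM, (n_hidden, λF) for the ANN."""

    svm_grid: tuple[tuple[float, float], ...]
    ann_grid: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.svm_grid or not self.ann_grid:
            raise ValueError("grids must be non-empty")

    @classmethod
    def default(cls, n_features: int = 8) -> "GridSpec":
        return cls(
            svm_grid=tuple(
                (C, g) for C in (0.1, 1.0, 10.0, 100.0) for g in (0.01, 0.1, 1.0 / n_features, 1.0)
            ),
            ann_grid=tuple((h, lr) for h in (4, 8, 16) for lr in (0.1, 0.5)),
        )

    @classmethod
    def small(cls, n_features: int = 8) -> "GridSpec":
        """A desk-scale grid for quick runs."""
        return cls(
            svm_grid=((1.0, 1.0 / n_features), (10.0, 0.1)),
            ann_grid=((8, 0.5), (16, 0.1)),
        )


def _preprocess_pair(
    train: LabeledDataset, test: LabeledDataset
) -> tuple[LabeledDataset, LabeledDataset, dict]:
    """Fit imputation + standardization on train; apply to both."""
    imp = fit_imputer(train)
    train_c = impute(imp, train)
    test_c = impute(imp, test)
    std = fit_standardizer(train_c)
    return (
        standardize(std, train_c),
        standardize(std, test_c),
        {"imputer_means": list(imp.means), "standardizer": {"loc": list(std.locations), "scale": list(std.scales)}},
    )


def _make_svm(params: tuple[float, float]) -> CalibratedSVM:
    C, gamma = params
    return CalibratedSVM(C=C, kernel=KernelSpec("rbf", gamma=gamma))


def _make_ann(params: tuple[int, float], seed: int, epochs: int) -> ANNClassifier:
    h, lr = params
    return ANNClassifier(ANNConfig(n_hidden=int(h), learning_rate=lr, epochs=epochs, seed=seed))


def grid_search(
    train: LabeledDataset,
    grid: GridSpec,
    inner_k: int = 3,
    seed: int = 0,
    ann_epochs: int = 100,
) -> dict:
    """Select (C, γ) and (n_hidden, λF) by mean inner-fold accuracy.

    Each inner fold refits preprocessing on its own training portion. Ties
    break by grid order (first candidate wins).
    """
    folds = stratified_kfold(train.labels, inner_k, seed=derive_seed(seed, "inner-folds"))
    splits = []
    for k in range(inner_k):
        tr = train.subset(folds.train_indices(k))
        te = train.subset(folds.test_indices(k))
        tr_s, te_s, _ = _preprocess_pair(tr, te)
        splits.append((tr_s, te_s))

    def best(candidates, fit_fn):
        scores = []
        for params in candidates:
            accs = []
            for tr_s, te_s in splits:
                clf = fit_fn(params).fit(tr_s)
                accs.append(float((clf.predict(te_s.values) == te_s.labels).mean()))
            scores.append(float(np.mean(accs)))
        return candidates[int(np.argmax(scores))], scores

    ann_seed = derive_seed(seed, "ann-inner")
    svm_choice, svm_scores = best(grid.svm_grid, _make_svm)
    ann_choice, ann_scores = best(
        grid.ann_grid, lambda p: _make_ann(p, ann_seed, ann_epochs)
    )
    return {
        "svm": svm_choice,
        "ann": ann_choice,
        "svm_scores": svm_scores,
        "ann_scores": ann_scores,
    }


@dataclass
class CVReport:
    """Per-fold metrics, mean±SD aggregates, pooled metrics, chosen hyperparams."""

    K: int
    seed: int
    per_fold: list  # one dict per outer fold
    aggregate: dict  # classifier -> metric -> (mean, sd)
    pooled: dict  # classifier -> MetricsReport
    chosen_hyperparams: list  # one dict per outer fold

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, MetricsReport):
                return asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o).__name__)

        return json.dumps(
            {
                "K": self.K,
                "seed": self.seed,
                "per_fold": self.per_fold,
                "aggregate": self.aggregate,
                "pooled": {c: asdict(r) for c, r in self.pooled.items()},
                "chosen_hyperparams": self.chosen_hyperparams,
            },
            default=enc,
        )


def aggregate(per_fold_values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample standard deviation (K-1 denominator) over folds."""
    v = np.asarray(per_fold_values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 folds to aggregate")
    return float(v.mean()), float(v.std(ddof=1))


def nested_cv(
    ds: LabeledDataset,
    grid: GridSpec | None = None,
    K: int = 5,
    inner_k: int = 3,
    seed: int = 0,
    ann_epochs: int = 100,
    rule: str = "mean",
    mode: str = "mean_posterior",
) -> CVReport:
    """Stratified nested cross-validation of SVM, ANN, and their fusion.

    Per outer fold: grid-search hyperparameters on the outer-train portion,
    refit preprocessing and all three classifiers on outer-train, evaluate
    on outer-test. Fusion priors and θ_i come from outer-train only.
    """
    grid = grid or GridSpec.default(ds.schema.n_features)
    folds = stratified_kfold(ds.labels, K, seed=derive_seed(seed, "outer-folds"))

    per_fold: list[dict] = []
    chosen_all: list[dict] = []
    pooled_truth: list[np.ndarray] = []
    pooled_pred: dict[str, list[np.ndarray]] = {c: [] for c in CLASSIFIERS}

    for k in range(K):
        tr_idx, te_idx = folds.train_indices(k), folds.test_indices(k)
        tr, te = ds.subset(tr_idx), ds.subset(te_idx)
        chosen = grid_search(
            tr, grid, inner_k=inner_k, seed=derive_seed(seed, f"grid-{k}"), ann_epochs=ann_epochs
        )
        tr_s, te_s, prep = _preprocess_pair(tr, te)

        svm = _make_svm(chosen["svm"]).fit(tr_s)
        ann = _make_ann(chosen["ann"], derive_seed(seed, f"ann-{k}"), ann_epochs).fit(tr_s)
        fm = FusionModel(
            members=[svm, ann],
            priors=ClassPriors.from_labels(tr_s.labels),
            rule=rule,
            mode=mode,
        )

        preds = {
            "svm": svm.predict(te_s.values),
            "ann": ann.predict(te_s.values),
            "fusion": fusion_predict(fm, te_s.values),
        }
        record: dict = {
            "fold": k,
            "train_indices": tr_idx.tolist(),
            "test_indices": te_idx.tolist(),
            "preprocessing": prep,
            "metrics": {},
        }
        for name, pred in preds.items():
            record["metrics"][name] = asdict(metrics(confusion(te.labels, pred)))
            pooled_pred[name].append(pred)
        pooled_truth.append(te.labels)
        per_fold.append(record)
        chosen_all.append({"svm": list(chosen["svm"]), "ann": list(chosen["ann"])})

    agg: dict = {}
    for name in CLASSIFIERS:
        agg[name] = {}
        for metric in per_fold[0]["metrics"][name]:
            vals = [rec["metrics"][name][metric] for rec in per_fold]
            m, s = aggregate(vals)
            agg[name][metric] = {"mean": m, "sd": s}

    truth = np.concatenate(pooled_truth)
    pooled = {
        name: metrics(confusion(truth, np.concatenate(pooled_pred[name])))
        for name in CLASSIFIERS
    }
    return CVReport(
        K=K,
        seed=seed,
        per_fold=per_fold,
        aggregate=agg,
        pooled=pooled,
        chosen_hyperparams=chosen_all,
    )
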