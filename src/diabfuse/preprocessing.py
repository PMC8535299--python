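"""Missing-value handling and Z-score standardization.

Two fitted, serializable transforms, always fit on training data and applied
to held-out data:

* mean imputation: a missing cell is replaced by the arithmetic mean of the
  feature's non-missing training cells;
* standardization: S(x) = (x - mean) / sd with the per-feature training mean
  and sample (n-1) standard deviation.

`mark_missing` applies the Pima zero-encoding convention: for features on the
schema's zero-is-missing list, a stored 0 means "not recorded" and becomes an
explicit missing cell.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .schema import FeatureSchema, LabeledDataset

__all__ = [
    "ImputationModel",
    "StandardizationModel",
    "mark_missing",
    "fit_imputer",
    "impute",
    "fit_standardizer",
    "standardize",
]


def mark_missing(ds: LabeledDataset) -> LabeledDataset:
    """Convert zeros to missing for features flagged zero-is-missing."""
    values = ds.values.copy()
    for name in ds.schema.zero_is_missing:
        j = ds.schema.index_of(name)
        values[values[:, j] == 0.0, j] = np.nan
    return ds.with_values(values)


@dataclass(frozen=True)
class ImputationModel:
    """Per-feature means over non-missing training cells."""

    means: tuple[float, ...]
    feature_names: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps({n: m for n, m in zip(self.feature_names, self.means)})

    @classmethod
    def from_json(cls, text: str, schema: FeatureSchema) -> "ImputationModel":
        obj = json.loads(text)
        return cls(
            means=tuple(float(obj[n]) for n in schema.names),
            feature_names=schema.names,
        )


def fit_imputer(train: LabeledDataset) -> ImputationModel:
    means = []
    for j, name in enumerate(train.schema.names):
        col = train.values[:, j]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"feature {name!r} has no observed training values")
        means.append(float(obs.mean()))
    return ImputationModel(means=tuple(means), feature_names=train.schema.names)


def impute(model: ImputationModel, ds: LabeledDataset) -> LabeledDataset:
    """Replace missing cells with training means; observed cells are untouched."""
    values = ds.values.copy()
    for j in range(values.shape[1]):
        mask = np.isnan(values[:, j])
        values[mask, j] = model.means[j]
    return ds.with_values(values)


@dataclass(frozen=True)
class StandardizationModel:
    """Per-feature (mean, sample SD) for the Z-score transform."""

    locations: tuple[float, ...]
    scales: tuple[float, ...]
    feature_names: tuple[str, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                n: {"mean": m, "sd": s}
                for n, m, s in zip(self.feature_names, self.locations, self.scales)
            }
        )

    @classmethod
    def from_json(cls, text: str, schema: FeatureSchema) -> "StandardizationModel":
        obj = json.loads(text)
        return cls(
            locations=tuple(float(obj[n]["mean"]) for n in schema.names),
            scales=tuple(float(obj[n]["sd"]) for n in schema.names),
            feature_names=schema.names,
        )


def fit_standardizer(train: LabeledDataset) -> StandardizationModel:
    if np.isnan(train.values).any():
        raise ValueError("standardizer requires a complete (imputed) dataset")
    loc, scale = [], []
    for j, name in enumerate(train.schema.names):
        col = train.values[:, j]
        sd = float(col.std(ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise ValueError(f"feature {name!r} is constant; cannot standardize")
        loc.append(float(col.mean()))
        scale.append(sd)
    return StandardizationModel(
        locations=tuple(loc), scales=tuple(scale), feature_names=train.schema.names
    )


def standardize(model: StandardizationModel, ds: LabeledDataset) -> LabeledDataset:
    if np.isnan(ds.values).any():
        raise ValueError("standardize requires a complete (imputed) dataset")
    loc = np.asarray(model.locations)
    scale = np.asarray(model.scales)
    return ds.with_values((ds.values - loc) / scale)


def unstandardize(model: StandardizationModel, ds: LabeledDataset) -> LabeledDataset:
    """Inverse of :func:`standardize` (the transform is affine and invertible)."""
    loc = np.asarray(model.locations)
    scale = np.asarray(model.scales)
    return ds.with_values(ds.values * scale + loc)
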