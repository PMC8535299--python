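"""Feature schema, labeled dataset container, and tabular CSV I/O.

The default schema is the 8-feature clinical profile shared by the Pima
Indian diabetes file and NHANES-derived extracts: glucose, pregnancies,
blood pressure, skin thickness, insulin, BMI, diabetes pedigree function
and age, plus a binary outcome column (0 = non-diabetic, 1 = diabetic).

Missing values are an explicit sentinel (NaN) distinct from zero; the
zero-to-missing convention of the Pima encoding is applied only by
:func:`diabfuse.preprocessing.mark_missing`, never silently at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_away

__all__ = [
    "Feature",
    "FeatureSchema",
    "LabeledDataset",
    "ClassSummary",
    "default_schema",
    "read_table",
    "write_table",
    "class_summary",
]


class SchemaError(ValueError):
    """A table does not conform to the expected feature schema."""


class ValidationError(ValueError):
    """A cell or label violates the dataset contract."""


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str  # "real" | "integer"
    unit: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaError("feature name must be non-empty")
        if self.kind not in ("real", "integer"):
            raise SchemaError(f"unknown feature kind {self.kind!r}")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature list plus the set of features whose zeros encode missingness."""

    features: tuple[Feature, ...]
    zero_is_missing: frozenset[str] = frozenset()
    label_name: str = "Outcome"

    def __post_init__(self) -> None:
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("feature names must be unique")
        unknown = self.zero_is_missing - set(names)
        if unknown:
            raise SchemaError(f"zero_is_missing names unknown features: {sorted(unknown)}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    @property
    def n_features(self) -> int:
        return len(self.features)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


#: Features whose value 0 is physiologically impossible and encodes "not recorded"
#: in the Pima-style files.
PIMA_ZERO_MISSING = frozenset(
    {"Glucose", "BloodPressure", "SkinThickness", "Insulin", "BMI"}
)


def default_schema(
    zero_is_missing: Iterable[str] | None = None, label_name: str = "Outcome"
) -> FeatureSchema:
    """The 8-feature diabetes schema (F1..F8), in canonical order."""
    features = (
        Feature("Glucose", "real", "mg/dL"),
        Feature("Pregnancies", "integer", "count"),
        Feature("BloodPressure", "real", "mm Hg"),
        Feature("SkinThickness", "real", "mm"),
        Feature("Insulin", "real", "mu U/mL"),
        Feature("BMI", "real", "kg/m^2"),
        Feature("DiabetesPedigreeFunction", "real", ""),
        Feature("Age", "integer", "years"),
    )
    zim = PIMA_ZERO_MISSING if zero_is_missing is None else frozenset(zero_is_missing)
    return FeatureSchema(features=features, zero_is_missing=zim, label_name=label_name)


@dataclass
class LabeledDataset:
    """n x d feature matrix with {0,1} labels and per-record source tags.

    ``values`` is a float array; missing cells are ``NaN``.
    """

    values: np.ndarray
    labels: np.ndarray
    sources: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(-1, self.schema.n_features)
        self.labels = np.asarray(self.labels, dtype=int)
        self.sources = np.asarray(self.sources, dtype=object)
        n, d = self.values.shape
        if d != self.schema.n_features:
            raise SchemaError(
                f"dataset has {d} columns, schema expects {self.schema.n_features}"
            )
        if self.labels.shape != (n,):
            raise ValidationError("labels length must equal number of rows")
        if self.sources.shape != (n,):
            raise ValidationError("sources length must equal number of rows")
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            raise ValidationError(
                f"label outside {{0,1}} at row {int(np.flatnonzero(bad)[0])}"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n

    def subset(self, idx: Sequence[int] | np.ndarray) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            sources=self.sources[idx].copy(),
            schema=self.schema,
        )

    def with_values(self, values: np.ndarray) -> "LabeledDataset":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.schema.names))
        df[self.schema.label_name] = self.labels
        return df


@dataclass(frozen=True)
class ClassSummary:
    """Per-class counts and 2-decimal percentages of a labeled dataset."""

    n_total: int
    n_per_class: tuple[int, int]  # (class 0, class 1)
    pct_per_class: tuple[float, float]


def read_table(
    path, schema: FeatureSchema, source: str | None = None
) -> LabeledDataset:
    """Read a header CSV into a :class:`LabeledDataset`.

    Non-numeric or empty feature cells become missing (NaN). The label
    column must parse to integers in {0, 1}.
    """
    df = pd.read_csv(path)
    required = list(schema.names) + [schema.label_name]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    values = np.column_stack(
        [pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float) for name in schema.names]
    ) if len(df) else np.empty((0, schema.n_features))
    raw_labels = pd.to_numeric(df[schema.label_name], errors="coerce")
    if raw_labels.isna().any() or not raw_labels.isin((0, 1)).all():
        row = int(np.flatnonzero(~raw_labels.isin((0, 1)).to_numpy())[0])
        raise ValidationError(f"label value outside {{0,1}} at row {row}")
    tag = source if source is not None else str(path)
    return LabeledDataset(
        values=values,
        labels=raw_labels.to_numpy(dtype=int),
        sources=np.array([tag] * len(df), dtype=object),
        schema=schema,
    )


def write_table(ds: LabeledDataset, path) -> None:
    """Write the dataset as a header CSV; missing cells become empty fields."""
    ds.to_frame().to_csv(path, index=False)


def class_summary(ds: LabeledDataset | np.ndarray) -> ClassSummary:
    """Counts and rounded percentages per class (0 = non-diabetic, 1 = diabetic)."""
    labels = ds.labels if isinstance(ds, LabeledDataset) else np.asarray(ds, dtype=int)
    n = labels.shape[0]
    if n == 0:
        raise ValidationError("cannot summarize an empty dataset")
    n1 = int((labels == 1).sum())
    n0 = n - n1
    pct = (round_half_away(100.0 * n0 / n), round_half_away(100.0 * n1 / n))
    return ClassSummary(n_total=n, n_per_class=(n0, n1), pct_per_class=pct)
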