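"""Seedable generator of multi-source synthetic diabetes-style tables.

Emulates the study conditions every stage is exercised under: two (or more)
tabular sources sharing the 8-feature schema, a two-class Gaussian feature
structure, class-1 prevalence ~33.5%, ages confined to 21-77 years, and
optional missingness on the clinically-can't-be-zero features.

The default class-conditional profiles loosely mimic published Pima class
summaries (higher glucose, BMI, age, pregnancies in the diabetic class);
they are documented stand-ins, not a clinical simulator. Features are drawn
independently per class; ``separation`` scales the class mean gap (1 = the
default overlap, 0 = identical classes / no signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import derive_seed
from .schema import FeatureSchema, LabeledDataset, default_schema

__all__ = ["SyntheticSpec", "generate", "inject_missing", "DEFAULT_CLASS_MEANS", "DEFAULT_CLASS_SDS"]

# (class 0, class 1) mean and shared SD per feature, schema order:
# Glucose, Pregnancies, BloodPressure, SkinThickness, Insulin, BMI, Pedigree, Age
DEFAULT_CLASS_MEANS = (
    (110.0, 142.0),
    (3.3, 4.9),
    (68.0, 71.0),
    (20.0, 23.0),
    (70.0, 101.0),
    (30.3, 35.1),
    (0.43, 0.55),
    (31.0, 37.0),
)
DEFAULT_CLASS_SDS = (25.0, 3.0, 18.0, 15.0, 95.0, 7.0, 0.30, 11.0)

AGE_RANGE = (21, 77)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-condition knobs for the generator.

    ``sources`` lists (name, n) per emulated source; ``prevalence`` is the
    Bernoulli probability of class 1 (diabetic); ``separation`` multiplies
    the class mean gap; ``missing_rate`` is the per-cell missingness
    probability on zero-is-missing features.
    """

    sources: tuple[tuple[str, int], ...] = (("nhanes-like", 9858), ("pima-like", 769))
    prevalence: float = 0.335
    class_means: tuple[tuple[float, float], ...] = DEFAULT_CLASS_MEANS
    class_sds: tuple[float, ...] = DEFAULT_CLASS_SDS
    separation: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sources or any(n < 1 for _, n in self.sources):
            raise ValueError("every source needs n >= 1")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if len(self.class_means) != 8 or len(self.class_sds) != 8:
            raise ValueError("class profiles must cover the 8 schema features")
        if any(s <= 0 for s in self.class_sds):
            raise ValueError("class SDs must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")


def generate(spec: SyntheticSpec, schema: FeatureSchema | None = None) -> list[LabeledDataset]:
    """Draw one LabeledDataset per source, deterministic given the seed."""
    schema = schema or default_schema()
    mu0 = np.array([m0 for m0, _ in spec.class_means])
    mu1_base = np.array([m1 for _, m1 in spec.class_means])
    mu1 = mu0 + spec.separation * (mu1_base - mu0)
    sds = np.array(spec.class_sds)

    integer_cols = [j for j, f in enumerate(schema.features) if f.kind == "integer"]
    age_j = schema.index_of("Age")
    preg_j = schema.index_of("Pregnancies")

    out = []
    for name, n in spec.sources:
        rng = np.random.default_rng(derive_seed(spec.seed, f"source:{name}"))
        labels = (rng.random(n) < spec.prevalence).astype(int)
        means = np.where(labels[:, None] == 1, mu1, mu0)
        values = rng.normal(means, sds)
        # physical constraints of the schema
        values = np.maximum(values, 0.0)
        values[:, age_j] = np.clip(values[:, age_j], *AGE_RANGE)
        values[:, preg_j] = np.maximum(values[:, preg_j], 0.0)
        for j in integer_cols:
            values[:, j] = np.rint(values[:, j])
        if spec.missing_rate > 0:
            ds = LabeledDataset(
                values=values,
                labels=labels,
                sources=np.array([name] * n, dtype=object),
                schema=schema,
            )
            ds = inject_missing(ds, spec.missing_rate, derive_seed(spec.seed, f"missing:{name}"))
            out.append(ds)
            continue
        out.append(
            LabeledDataset(
                values=values,
                labels=labels,
                sources=np.array([name] * n, dtype=object),
                schema=schema,
            )
        )
    return out


def inject_missing(ds: LabeledDataset, rate: float, seed: int = 0) -> LabeledDataset:
    """Independently blank eligible cells with the given probability.

    Only features on the schema's zero-is-missing list are eligible; labels
    are never touched.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return ds
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    for name in ds.schema.zero_is_missing:
        j = ds.schema.index_of(name)
        mask = rng.random(ds.n) < rate
        values[mask, j] = np.nan
    return ds.with_values(values)
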