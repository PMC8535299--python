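"""Dataset-level fusion (Data In - Data Out).

Multiple tabular sources sharing the 8-feature schema are aligned by column
name and concatenated into one dataset, preserving per-record source tags.
This is the raw-data fusion level: records in, cleaner merged records out.
Optional exact-duplicate collapsing keeps the first occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .schema import FeatureSchema, LabeledDataset, SchemaError

__all__ = ["FusionReport", "fuse_datasets"]


@dataclass
class FusionReport:
    n_in_per_source: dict[str, int]
    n_out: int
    duplicates_removed: int
    conflict_log: list = field(default_factory=list)


def fuse_datasets(
    sources: Sequence[LabeledDataset],
    schema: FeatureSchema,
    dedup: bool = False,
) -> tuple[LabeledDataset, FusionReport]:
    """Concatenate schema-conforming sources into one dataset.

    Every source must carry the same features (aligned by name); a mismatch
    raises :class:`SchemaError` naming the offending source and column. With
    ``dedup`` on, rows identical in all feature values and the label across
    sources are collapsed to their first occurrence.
    """
    if not sources:
        raise ValueError("need at least one source dataset")
    for i, src in enumerate(sources):
        if src.schema.names != schema.names:
            extra = set(src.schema.names) - set(schema.names)
            missing = set(schema.names) - set(src.schema.names)
            col = sorted(missing or extra or {"<order>"})[0]
            tag = src.sources[0] if src.n else f"source[{i}]"
            raise SchemaError(f"source {tag!r} does not match schema at column {col!r}")

    values = np.vstack([s.values for s in sources])
    labels = np.concatenate([s.labels for s in sources])
    tags = np.concatenate([s.sources for s in sources])

    n_in: dict[str, int] = {}
    for s in sources:
        for t in s.sources:
            n_in[t] = n_in.get(t, 0) + 1

    removed = 0
    if dedup:
        df = pd.DataFrame(values)
        df["__label__"] = labels
        keep = ~df.duplicated(keep="first").to_numpy()
        removed = int((~keep).sum())
        values, labels, tags = values[keep], labels[keep], tags[keep]

    fused = LabeledDataset(values=values, labels=labels, sources=tags, schema=schema)
    report = FusionReport(
        n_in_per_source=n_in,
        n_out=fused.n,
        duplicates_removed=removed,
    )
    return fused, report
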