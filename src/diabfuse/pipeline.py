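"""End-to-end workflow: input -> fuse -> preprocess -> nested CV -> fused
classifier -> evaluation artifacts.

The configuration names either CSV input paths or a synthetic-data spec
(exactly one), plus schema, fusion, and cross-validation options. One global
seed is fanned out to stage-specific derived seeds so each stage is
independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._util import derive_seed
from .ann import ANNClassifier, ANNConfig
from .decision import ClassPriors, FusionModel
from .evaluation import format_table, MetricsReport
from .fuse import fuse_datasets
from .preprocessing import fit_imputer, fit_standardizer, impute, mark_missing, standardize
from .schema import class_summary, default_schema, read_table, write_table
from .synthetic import SyntheticSpec, generate
from .validation import GridSpec, nested_cv

log = logging.getLogger("diabfuse")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_paths: list[str] | None = None
    synthetic: SyntheticSpec | None = None
    zero_is_missing: list[str] | None = None
    label_name: str = "Outcome"
    rule: str = "mean"
    mode: str = "mean_posterior"
    k_folds: int = 5
    inner_k: int = 3
    grid: GridSpec | None = None
    ann_epochs: int = 100
    seed: int = 0
    outdir: str = "diabfuse-out"
    dedup: bool = False

    def __post_init__(self) -> None:
        has_paths = bool(self.input_paths)
        has_synth = self.synthetic is not None
        if has_paths == has_synth:
            raise ValueError("exactly one of input paths / synthetic spec must be given")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        if synth is not None:
            if "sources" in synth:
                synth["sources"] = tuple((s["name"], int(s["n"])) for s in synth["sources"])
            synth = SyntheticSpec(**synth)
        grid = raw.pop("grid", None)
        if grid is not None:
            grid = GridSpec(
                svm_grid=tuple(tuple(c) for c in grid["svm"]),
                ann_grid=tuple(tuple(c) for c in grid["ann"]),
            )
        raw = {k: v for k, v in raw.items() if v is not None}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(synthetic=synth, grid=grid, **raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and write artifacts to the output directory.

    Returns a manifest dict of the artifacts written. Stages: input, data
    fusion, zero-to-missing marking, nested stratified CV (per-fold
    preprocessing + grid search + SVM/ANN/fusion training and evaluation),
    final model fit on all data, metrics table.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    schema = default_schema(
        zero_is_missing=config.zero_is_missing, label_name=config.label_name
    )
    t0 = time.time()

    if config.synthetic is not None:
        sources = generate(config.synthetic, schema)
    else:
        sources = [read_table(p, schema) for p in config.input_paths]
    log.info("input: %d source(s), %s records", len(sources), [s.n for s in sources])

    fused, freport = fuse_datasets(sources, schema, dedup=config.dedup)
    fused = mark_missing(fused)
    write_table(fused, outdir / "fused.csv")
    summary = class_summary(fused)
    log.info(
        "fused %d records; class split %s / %s%%",
        fused.n,
        summary.n_per_class,
        summary.pct_per_class,
    )

    grid = config.grid or GridSpec.small(schema.n_features)
    report = nested_cv(
        fused,
        grid=grid,
        K=config.k_folds,
        inner_k=config.inner_k,
        seed=config.seed,
        ann_epochs=config.ann_epochs,
        rule=config.rule,
        mode=config.mode,
    )
    (outdir / "cv_report.json").write_text(report.to_json())

    table = format_table({name.upper(): rep for name, rep in report.pooled.items()})
    (outdir / "metrics_table.txt").write_text(table + "\n")
    log.info("pooled CV metrics:\n%s", table)

    # final models on the full fused dataset with the modal chosen hyperparams
    svm_params = _modal([tuple(c["svm"]) for c in report.chosen_hyperparams])
    ann_params = _modal([tuple(c["ann"]) for c in report.chosen_hyperparams])
    imp = fit_imputer(fused)
    complete = impute(imp, fused)
    std = fit_standardizer(complete)
    ready = standardize(std, complete)

    from .validation import _make_ann, _make_svm  # shared constructors

    svm = _make_svm(svm_params).fit(ready)
    ann = _make_ann(ann_params, derive_seed(config.seed, "ann-final"), config.ann_epochs).fit(ready)
    fm = FusionModel(
        members=[svm, ann],
        priors=ClassPriors.from_labels(ready.labels),
        rule=config.rule,
        mode=config.mode,
    )
    (outdir / "svm_model.json").write_text(svm.model.to_json())
    (outdir / "svm_calibration.json").write_text(
        json.dumps({"A": svm.calibration.A, "B": svm.calibration.B})
    )
    (outdir / "ann_model.json").write_text(ann.model.to_json())
    (outdir / "preprocessing.json").write_text(
        json.dumps(
            {
                "imputer": json.loads(imp.to_json()),
                "standardizer": json.loads(std.to_json()),
            }
        )
    )
    (outdir / "fusion_manifest.json").write_text(
        json.dumps(
            {
                "members": ["svm_model.json", "ann_model.json"],
                "svm_calibration": "svm_calibration.json",
                "priors": {"p_target": fm.priors.p_target, "p_outlier": fm.priors.p_outlier},
                "theta_i": list(fm.theta_i),
                "rule": fm.rule,
                "mode": fm.mode,
                "threshold": fm.threshold,
            }
        )
    )
    manifest = {
        "outdir": str(outdir),
        "n_records": fused.n,
        "duplicates_removed": freport.duplicates_removed,
        "class_summary": {
            "counts": list(summary.n_per_class),
            "percent": list(summary.pct_per_class),
        },
        "pooled_accuracy": {c: report.pooled[c].accuracy for c in report.pooled},
        "elapsed_s": round(time.time() - t0, 2),
        "artifacts": sorted(p.name for p in outdir.iterdir()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _modal(items: list) -> tuple:
    vals, counts = np.unique([repr(i) for i in items], return_counts=True)
    winner = vals[int(np.argmax(counts))]
    for i in items:
        if repr(i) == winner:
            return i
    raise AssertionError("unreachable")
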