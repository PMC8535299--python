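"""Confusion matrix and the seven-entry evaluation matrix.

Class 1 (diabetic) is the positive class. Percent metrics (accuracy, miss
rate, sensitivity, specificity, precision) are on a 0-100 scale; the false
positive/negative ratios are proportions in [0, 1]:

    accuracy    = (TP + TN) / n * 100
    miss rate   = (FP + FN) / n * 100            (= 100 - accuracy)
    sensitivity = TP / (TP + FN) * 100           (recall)
    specificity = TN / (TN + FP) * 100
    precision   = TP / (TP + FP) * 100
    FPR         = 1 - specificity / 100
    FNR         = 1 - sensitivity / 100

Internal values keep full precision; rounding (half away from zero, two
decimals) happens only at presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from ._util import round_half_away

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "compare_reports", "format_table"]

METRIC_NAMES = (
    "accuracy",
    "specificity",
    "sensitivity",
    "precision",
    "miss_rate",
    "fpr",
    "fnr",
)


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    miss_rate: float
    sensitivity: float
    specificity: float
    precision: float
    fpr: float
    fnr: float

    @classmethod
    def from_rates(
        cls,
        accuracy: float,
        sensitivity: float,
        specificity: float,
        precision: float = math.nan,
    ) -> "MetricsReport":
        """Build a report from headline percentages, deriving the complements.

        Useful for comparing against published tables where only accuracy,
        sensitivity, specificity and precision are printed.
        """
        return cls(
            accuracy=accuracy,
            miss_rate=100.0 - accuracy,
            sensitivity=sensitivity,
            specificity=specificity,
            precision=precision,
            fpr=1.0 - specificity / 100.0,
            fnr=1.0 - sensitivity / 100.0,
        )

    def rounded(self) -> dict[str, float]:
        return {f.name: round_half_away(getattr(self, f.name)) for f in fields(self)}


def confusion(truth, pred) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError("truth and prediction must be equal-length 1-D sequences")
    if truth.size == 0:
        raise ValueError("cannot build a confusion matrix from no predictions")
    return ConfusionMatrix(
        tp=int(((truth == 1) & (pred == 1)).sum()),
        tn=int(((truth == 0) & (pred == 0)).sum()),
        fp=int(((truth == 0) & (pred == 1)).sum()),
        fn=int(((truth == 1) & (pred == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity") * 100.0
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity") * 100.0
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision") * 100.0
    acc = (cm.tp + cm.tn) / n * 100.0
    return MetricsReport(
        accuracy=acc,
        miss_rate=(cm.fp + cm.fn) / n * 100.0,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        fpr=1.0 - spec / 100.0,
        fnr=1.0 - sens / 100.0,
    )


def compare_reports(a: MetricsReport, b: MetricsReport) -> dict[str, float]:
    """Per-metric margin a - b (percentage points for percent metrics)."""
    return {name: getattr(a, name) - getattr(b, name) for name in METRIC_NAMES}


def format_table(reports: dict[str, MetricsReport]) -> str:
    """Aligned text table, metrics as rows and classifiers as columns."""
    labels = {
        "accuracy": "Accuracy",
        "specificity": "Specificity",
        "sensitivity": "Sensitivity",
        "precision": "Precision",
        "miss_rate": "Miss rate",
        "fpr": "False Positive Ratio (FPR)",
        "fnr": "False Negative Ratio (FNR)",
    }
    cols = list(reports)
    width = max(len(labels[m]) for m in METRIC_NAMES) + 2
    head = "Evaluation Matrix".ljust(width) + "".join(c.rjust(12) for c in cols)
    lines = [head]
    for m in METRIC_NAMES:
        pct = m not in ("fpr", "fnr")
        row = labels[m].ljust(width)
        for c in cols:
            v = round_half_away(getattr(reports[c], m))
            row += (f"{v:.2f}%" if pct else f"{v:.2f}").rjust(12)
        lines.append(row)
    return "\n".join(lines)
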