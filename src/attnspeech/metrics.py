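"""Evaluation metrics for two-class depression detection.

The primary metric is the unweighted average recall (UAR): the mean of
per-class recalls.  Unlike accuracy, UAR is insensitive to class imbalance,
which matters because clinical speech corpora rarely have balanced
depression / control counts.  Precision, recall and F1 follow the standard
confusion-matrix definitions, and a box-plot style stability summary
condenses UARs observed across repeated evaluation checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "confusion_from_predictions",
    "uar",
    "precision_recall_f1",
    "StabilitySummary",
    "stability_summary",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: tuple[str, ...] = ("control", "depression")

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"confusion matrix must be square, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("confusion matrix entries must be non-negative")
        if len(self.class_names) != counts.shape[0]:
            raise ValueError("class_names length must match matrix order")
        object.__setattr__(self, "counts", counts)

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def class_support(self, i: int) -> int:
        """n_i: number of evaluated samples whose true class is i."""
        return int(self.counts[i].sum())


def confusion_from_predictions(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    class_names: tuple[str, ...] = ("control", "depression"),
) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    n = len(class_names)
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names)


def uar(cm: ConfusionMatrix) -> float:
    """Unweighted average recall: (1/N) * sum_i c_i / n_i.

    c_i is the diagonal count (correctly classified samples of class i) and
    n_i the class support.  Raises if any true class has no samples, since
    its recall would be undefined.
    """
    counts = cm.counts
    support = counts.sum(axis=1)
    empty = np.nonzero(support == 0)[0]
    if empty.size:
        names = ", ".join(cm.class_names[i] for i in empty)
        raise ValueError(f"UAR undefined: no evaluated samples for class(es) {names}")
    recalls = np.diag(counts) / support
    return float(recalls.mean())


def precision_recall_f1(
    cm: ConfusionMatrix, positive_class: int = 1
) -> tuple[float, float, float]:
    """Precision, recall and F1 for one class treated as positive.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2*precision*recall/(precision+recall), with F1 = 0 when both
    precision and recall are 0.
    """
    counts = cm.counts
    p = positive_class
    tp = counts[p, p]
    fp = counts[:, p].sum() - tp
    fn = counts[p, :].sum() - tp
    if tp + fn == 0:
        raise ValueError(
            f"recall undefined: no true samples of positive class "
            f"{cm.class_names[p]!r}"
        )
    if tp + fp == 0:
        raise ValueError(
            f"precision undefined: class {cm.class_names[p]!r} was never predicted"
        )
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f1)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass(frozen=True)
class StabilitySummary:
    """Box-plot style summary of UARs across evaluation checkpoints.

    The median is the "stable" UAR; whiskers extend to the most extreme
    observations within 1.5*IQR of the quartiles, and points beyond are
    flagged as outliers.
    """

    uars: tuple[float, ...]
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...] = field(default_factory=tuple)


def stability_summary(uar_list: Sequence[float]) -> StabilitySummary:
    values = np.asarray(uar_list, dtype=float)
    if values.size == 0:
        raise ValueError("stability summary requires at least one UAR")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return StabilitySummary(
        uars=tuple(float(v) for v in values),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=tuple(float(v) for v in np.sort(outliers)),
    )
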