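"""Segmentation evaluation: confusion matrix, Dice, accuracy, mPA and mIoU.

Dice is reported as a fraction in [0,1]; accuracy, mPA (mean per-class pixel
recall) and mIoU (mean per-class intersection-over-union) as percentages.
Classes absent from the ground truth are skipped with the divisor
renormalized; Dice of two empty regions is defined as 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import MaskStack, SegmentationMask

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "dice",
           "accuracy", "mpa", "miou", "report_from_confusion",
           "pooled_confusion"]


@dataclass
class ConfusionMatrix:
    """counts[i, j] = pixels with true label i predicted as j."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def k(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    # binary shorthand (class 1 = damage)
    @property
    def tp(self) -> int:
        return int(self.counts[1, 1])

    @property
    def tn(self) -> int:
        return int(self.counts[0, 0])

    @property
    def fp(self) -> int:
        return int(self.counts[0, 1])

    @property
    def fn(self) -> int:
        return int(self.counts[1, 0])

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.counts + other.counts)


@dataclass
class MetricsReport:
    dice: float
    miou: float
    mpa: float
    accuracy: float

    def as_dict(self) -> dict:
        return {"dice": self.dice, "miou": self.miou, "mpa": self.mpa,
                "accuracy": self.accuracy}


def _labels(m) -> np.ndarray:
    return m.labels if isinstance(m, SegmentationMask) else np.asarray(m)


def confusion(pred, truth, k: int = 1) -> ConfusionMatrix:
    p, t = _labels(pred), _labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    if p.max(initial=0) > k or t.max(initial=0) > k:
        raise ValueError(f"labels exceed declared maximum k={k}")
    idx = t.astype(np.int64).ravel() * (k + 1) + p.astype(np.int64).ravel()
    counts = np.bincount(idx, minlength=(k + 1) ** 2).reshape(k + 1, k + 1)
    return ConfusionMatrix(counts)


def pooled_confusion(preds: MaskStack | list, truths: MaskStack | list,
                     k: int = 1) -> ConfusionMatrix:
    cm = ConfusionMatrix(np.zeros((k + 1, k + 1), dtype=np.int64))
    for p, t in zip(preds, truths):
        cm = cm + confusion(p, t, k)
    return cm


def dice(cm: ConfusionMatrix) -> float:
    """2|X∩Y| / (|X|+|Y|) for the foreground class; 1.0 when both empty."""
    if cm.k != 1:
        raise ValueError("dice is defined for the binary confusion matrix")
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        return 1.0
    return 2.0 * cm.tp / denom

def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def mpa(cm: ConfusionMatrix) -> float:
    """Mean per-class pixel recall (percent), absent classes skipped."""
    row = cm.counts.sum(axis=1)
    present = row > 0
    if not present.any():
        raise ValueError("no class present in ground truth")
    recalls = np.diag(cm.counts)[present] / row[present]
    return 100.0 * float(recalls.mean())


def miou(cm: ConfusionMatrix) -> float:
    """Mean intersection-over-union (percent), absent classes skipped."""
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    diag = np.diag(cm.counts)
    present = row > 0
    if not present.any():
        raise ValueError("no class present in ground truth")
    union = (row + col - diag)[present]
    return 100.0 * float((diag[present] / union).mean())


def report_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    return MetricsReport(dice=dice(cm), miou=miou(cm), mpa=mpa(cm),
                         accuracy=accuracy(cm))
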