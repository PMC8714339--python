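"""Pixel-level segmentation evaluation: IoU, precision, recall.

Evaluation is binary: the mask is collapsed to target vs non-target at a
chosen class id (lesion, class 3, by default in the pipeline) and pixels are
tallied into a confusion table.  The three scores are the standard
count-based definitions

    IoU       = TP / (TP + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)

where TP are target pixels detected as target, FP non-target pixels detected
as target, and FN target pixels missed.  A score whose denominator is zero is
*undefined* and returned as ``None`` — never silently 0 — so that dataset
aggregation can skip or flag images with no target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a binary segmentation comparison."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def confusion(pred: np.ndarray, truth: np.ndarray, target_class: int) -> ConfusionCounts:
    """Collapse both masks to binary at ``target_class`` and tally pixels."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p = pred == target_class
    t = truth == target_class
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def iou(c: ConfusionCounts) -> float | None:
    """Overlap of predicted and true target sets over their union."""
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else None


def precision(c: ConfusionCounts) -> float | None:
    """Fraction of detected target pixels that are truly target."""
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def recall(c: ConfusionCounts) -> float | None:
    """Fraction of true target pixels that were detected."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def pixel_accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total


def summarize(c: ConfusionCounts) -> dict:
    """All scores plus the raw counts, as a JSON-friendly dict."""
    return {
        "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
        "iou": iou(c), "precision": precision(c), "recall": recall(c),
        "pixel_accuracy": pixel_accuracy(c),
    }
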