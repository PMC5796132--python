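"""Identification-accuracy metrics: SE, SP, ACC (percent) and MCC.

    SE  = TP / (TP + FN) * 100
    SP  = TN / (TN + FP) * 100
    ACC = (TP + TN) / (TP + FN + TN + FP) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))

A metric whose denominator (or any MCC factor) is zero is *undefined* and
reported as NaN, never as 0; aggregation and paired comparisons drop
undefined values pairwise. With the heavily negative-dominated independent
sets used here, ACC tracks SP closely, which is why MCC is the headline
stability metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .records import POSITIVE

UNDEFINED = float("nan")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _as_bool(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype != bool:
        arr = arr == POSITIVE
    return arr


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Tally the four joint outcomes of predicted vs true binary labels."""
    pred = _as_bool(predicted)
    true = _as_bool(truth)
    if pred.shape != true.shape:
        raise ValueError(
            f"label length mismatch: {pred.shape} vs {true.shape}"
        )
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def sensitivity(c: ConfusionCounts) -> float:
    """Percent of true positives called positive (recall)."""
    denom = c.tp + c.fn
    return UNDEFINED if denom == 0 else 100.0 * c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """Percent of true negatives called negative."""
    denom = c.tn + c.fp
    return UNDEFINED if denom == 0 else 100.0 * c.tn / denom


def accuracy(c: ConfusionCounts) -> float:
    """Percent of all samples called correctly."""
    return UNDEFINED if c.total == 0 else 100.0 * (c.tp + c.tn) / c.total


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; NaN if any factor is 0."""
    factors = (
        (c.tp + c.fn) * (c.tp + c.fp),
        (c.tn + c.fp) * (c.tn + c.fn),
    )
    if factors[0] == 0 or factors[1] == 0:
        return UNDEFINED
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(factors[0] * factors[1])


def metric_row(c: ConfusionCounts) -> dict[str, float]:
    return {
        "se": sensitivity(c),
        "sp": specificity(c),
        "acc": accuracy(c),
        "mcc": mcc(c),
    }
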