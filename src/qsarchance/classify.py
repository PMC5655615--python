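"""Confusion-matrix construction and threshold classification metrics.

Six metrics are computed from the confusion counts: accuracy, precision,
sensitivity (recall), specificity, fall-out (1 − specificity) and F1.
A metric whose denominator is zero is NaN, not 0 — an undefined precision is
not a zero precision.  F1 is computed from the counts as
``2·TP / (2·TP + FP + FN)``; the harmonic-mean form
``2·PREC·SENS/(PREC + SENS)`` agrees exactly whenever both rates are
defined.  Reports round to 2 decimals; internals keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ContractError

__all__ = ["ConfusionCounts", "ClassificationMetrics", "confusion", "classification_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0 or int(v) != v:
                raise ContractError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassificationMetrics:
    acc: float
    prec: float
    sens: float
    spec: float
    fall: float
    f1: float

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        return {k: round(v, ndigits) for k, v in self.__dict__.items()}

    def as_array(self) -> np.ndarray:
        return np.array([self.acc, self.prec, self.sens, self.spec, self.fall, self.f1])


METRIC_NAMES = ("acc", "prec", "sens", "spec", "fall", "f1")


def confusion(
    true_labels: Sequence[int],
    predicted_labels: Sequence[int],
    positive_label: int = 1,
) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary 0/1 label vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ContractError("label vectors have different lengths")
    for name, v in (("true", t), ("predicted", p)):
        bad = set(np.unique(v).tolist()) - {0, 1}
        if bad:
            raise ContractError(f"{name} labels must be binary 0/1, got {sorted(bad)}")
    pos = t == positive_label
    pred_pos = p == positive_label
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """The six threshold metrics from confusion counts (NaN on zero
    denominators)."""
    if counts.total == 0:
        raise ContractError("all confusion counts are zero")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    spec = _ratio(tn, tn + fp)
    return ClassificationMetrics(
        acc=_ratio(tp + tn, counts.total),
        prec=_ratio(tp, tp + fp),
        sens=_ratio(tp, tp + fn),
        spec=spec,
        fall=1.0 - spec if not math.isnan(spec) else float("nan"),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )
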