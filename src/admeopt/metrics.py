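"""Confusion-matrix statistics, informedness, ROC/AUC, and dispersion.

Conventions: the positive class is *deleterious* (a variant with a
functional impact in vitro). Calls of ``None`` are treated as missing and
excluded from every count. Metrics whose denominator is empty raise
:class:`UndefinedMetricError` rather than silently returning 0 or NaN —
an undefined sensitivity is not a sensitivity of zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn import metrics as _skm

from .dataset import Label
from .errors import UndefinedMetricError, ValidationError
from .registry import Direction

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "accuracy",
    "informedness",
    "roc_curve",
    "auc",
    "coefficient_of_variation",
    "UndefinedMetricError",
]

MISSING = None  # sentinel for a call no algorithm could make


def _as_label(x) -> Optional[Label]:
    if x is None:
        return None
    if isinstance(x, Label):
        return x
    if isinstance(x, str):
        if x == "missing":
            return None
        return Label(x)
    raise ValidationError(f"not a call: {x!r}")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 classification counts with deleterious as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )


def confusion(labels: Sequence, calls: Sequence) -> ConfusionCounts:
    """Tally calls against labels; missing calls are excluded entirely."""
    if len(labels) != len(calls):
        raise ValidationError(
            f"labels ({len(labels)}) and calls ({len(calls)}) differ in length"
        )
    tp = fp = tn = fn = 0
    for lab, call in zip(labels, calls):
        call = _as_label(call)
        if call is None:
            continue
        lab = _as_label(lab)
        if lab is Label.DELETERIOUS:
            if call is Label.DELETERIOUS:
                tp += 1
            else:
                fn += 1
        else:
            if call is Label.NEUTRAL:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        raise UndefinedMetricError(f"{name} undefined: empty denominator")
    return num / den


def sensitivity(c: ConfusionCounts) -> float:
    """True positive rate: TP / (TP + FN)."""
    return _ratio(c.tp, c.tp + c.fn, "sensitivity")


def specificity(c: ConfusionCounts) -> float:
    """True negative rate: TN / (TN + FP)."""
    return _ratio(c.tn, c.tn + c.fp, "specificity")


def ppv(c: ConfusionCounts) -> float:
    """Positive predictive value: TP / (TP + FP)."""
    return _ratio(c.tp, c.tp + c.fp, "ppv")


def npv(c: ConfusionCounts) -> float:
    """Negative predictive value: TN / (TN + FN)."""
    return _ratio(c.tn, c.tn + c.fn, "npv")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    return _ratio(c.tp + c.tn, c.n, "accuracy")


def informedness(c: ConfusionCounts) -> float:
    """Youden index J = sensitivity + specificity - 1, in [-1, 1].

    Interpretable as the probability of an informed (rather than chance)
    classification; requires both classes present.
    """
    return sensitivity(c) + specificity(c) - 1.0


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points as parallel arrays, (0,0) first and (1,1) last.

    ``thresholds`` are in the algorithm's original score units; the first
    entry is the no-call extreme (+/- infinity depending on orientation).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist(), self.thresholds.tolist()))


def _drop_missing(scores, labels):
    kept_scores, kept_labels = [], []
    for s, lab in zip(scores, labels):
        if s is None or (isinstance(s, float) and math.isnan(s)):
            continue
        kept_scores.append(float(s))
        kept_labels.append(_as_label(lab))
    return np.asarray(kept_scores), kept_labels


def roc_curve(scores: Sequence, labels: Sequence, direction: Direction) -> RocCurve:
    """ROC curve oriented so that "more deleterious" raises TPR first.

    One operating point per distinct observed score plus the (0,0)
    endpoint; missing scores are dropped before the sweep.
    """
    if len(scores) != len(labels):
        raise ValidationError("scores and labels differ in length")
    s, labs = _drop_missing(scores, labels)
    y = np.array([1 if lab is Label.DELETERIOUS else 0 for lab in labs])
    if len(y) == 0 or y.min() == y.max():
        raise ValidationError("ROC requires at least one variant in each class")
    oriented = -s if direction is Direction.LESS else s
    fpr, tpr, thr = _skm.roc_curve(y, oriented, drop_intermediate=False)
    if direction is Direction.LESS:
        thr = -thr
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the rank statistic P(score_deleterious > score_neutral) with
    ties counted half.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """|CV| = |sample sd / mean|, with the n-1 standard deviation.

    Used to summarize how much a fold-optimal threshold moves between
    cross-validation folds.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        raise ValidationError("|CV| requires at least two values")
    mean = vals.mean()
    if mean == 0:
        raise UndefinedMetricError("|CV| undefined: mean is zero")
    return float(abs(vals.std(ddof=1) / mean))
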