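"""Evaluation suite: confusion matrices, accuracy/sensitivity/specificity/
precision/F1, and the Sørensen–Dice overlap index.

The positive class is *mitosis* everywhere in this package. Metrics are
stored as fractions in [0, 1]; :meth:`MetricsReport.percent` renders the
two-decimal percentage form used in result tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from mitoscope.errors import ValidationError

POSITIVE_LABEL = "mitosis"


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with mitosis as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricsReport:
    """Derived classification metrics, each a fraction in [0, 1].

    ``degenerate`` flags that at least one ratio had a zero denominator and
    was reported as 0 by convention (also emitted as a RuntimeWarning).
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    degenerate: bool = False

    def percent(self, ndigits: int = 2) -> dict[str, float]:
        """Metrics as percentages rounded to ``ndigits`` decimals."""
        return {
            k: round(getattr(self, k) * 100, ndigits)
            for k in ("accuracy", "sensitivity", "specificity", "precision", "f1")
        }


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, sensitivity, specificity, precision and F1 from counts.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), precision = TP/(TP+FP),
    F1 = 2·precision·recall/(precision+recall).
    Zero denominators yield 0 with a warning flag (declared convention).
    """
    if cm.total == 0:
        raise ValidationError("confusion matrix is empty")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity, d1 = _ratio(cm.tp, cm.tp + cm.fn)
    specificity, d2 = _ratio(cm.tn, cm.tn + cm.fp)
    precision, d3 = _ratio(cm.tp, cm.tp + cm.fp)
    f1, d4 = _ratio(2 * precision * sensitivity, precision + sensitivity)
    degenerate = d1 or d2 or d3 or d4
    if degenerate:
        warnings.warn("zero denominator in a classification metric; reported as 0",
                      RuntimeWarning, stacklevel=2)
    return MetricsReport(accuracy, sensitivity, specificity, precision, f1, degenerate)


def dice(predicted_mask: np.ndarray, truth_mask: np.ndarray, *, factor_two: bool = True) -> float:
    """Sørensen–Dice coefficient 2|Ŷ∩Y| / (|Ŷ|+|Y|) between binary masks.

    Both masks empty returns 1.0 (declared convention). With
    ``factor_two=False`` the un-doubled overlap ratio |Ŷ∩Y|/(|Ŷ|+|Y|) is
    returned instead (bounded by 0.5; kept for auditing variant formulas).
    """
    pred = np.asarray(predicted_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ValidationError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    inter = np.logical_and(pred, truth).sum()
    return (2.0 if factor_two else 1.0) * inter / denom


def confusion_from_predictions(labels, predictions) -> ConfusionMatrix:
    """Tally a ConfusionMatrix from parallel binary label/prediction lists.

    Entries may be 0/1 integers, booleans, or the string labels
    ``mitosis``/``not_mitosis``.
    """
    y = _as_binary(labels, "labels")
    p = _as_binary(predictions, "predictions")
    if y.shape != p.shape:
        raise ValidationError(f"length mismatch: {y.size} labels vs {p.size} predictions")
    tp = int(np.sum(y & p))
    fn = int(np.sum(y & ~p))
    fp = int(np.sum(~y & p))
    tn = int(np.sum(~y & ~p))
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def _as_binary(values, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "US":
        known = {POSITIVE_LABEL, "not_mitosis"}
        bad = set(arr.tolist()) - known
        if bad:
            raise ValidationError(f"unknown {what}: {sorted(bad)}")
        return arr == POSITIVE_LABEL
    uniq = set(np.unique(arr).tolist())
    if not uniq <= {0, 1, True, False}:
        raise ValidationError(f"{what} must be binary, got values {sorted(uniq)}")
    return arr.astype(bool)
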