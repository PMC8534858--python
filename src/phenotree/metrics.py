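"""Confusion-matrix accounting and the six performance metrics.

Accuracy, sensitivity (recall), specificity, positive and negative
predictive value, and the F1-score — the harmonic mean of precision and
recall, the preferred summary under class imbalance:

    F1 = 2 * recall * precision / (recall + precision)

Metrics with a zero denominator are reported as NaN (not-a-value), never
as 0: a classifier that makes no positive calls has an *undefined*
precision, not a bad one. F1 is likewise NaN when either precision or
recall is zero or undefined.

``reconstruct_cm`` inverts printed sensitivity/specificity back to integer
confusion counts (round half-up), which is how published performance tables
can be checked for internal consistency.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .errors import ConfigurationError


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int).ravel()
        y_pred = np.asarray(y_pred).astype(int).ravel()
        if len(y_true) != len(y_pred):
            raise ValueError("label vectors are misaligned")
        return cls(
            TP=int(np.sum((y_true == 1) & (y_pred == 1))),
            FP=int(np.sum((y_true == 0) & (y_pred == 1))),
            FN=int(np.sum((y_true == 1) & (y_pred == 0))),
            TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        )


@dataclasses.dataclass(frozen=True)
class PerformanceReport:
    """The six headline metrics, each in [0, 1] or NaN when undefined."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PerformanceReport":
        return cls(**{f.name: float(d[f.name]) for f in dataclasses.fields(cls)})

    def isclose(self, other: "PerformanceReport", tol: float = 1e-12) -> bool:
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if math.isnan(a) != math.isnan(b):
                return False
            if not math.isnan(a) and abs(a - b) > tol:
                return False
        return True


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def performance(cm: ConfusionMatrix) -> PerformanceReport:
    """Derive the six metrics from a confusion matrix."""
    if cm.N == 0:
        raise ConfigurationError("empty confusion matrix")
    sens = _ratio(cm.TP, cm.TP + cm.FN)
    ppv = _ratio(cm.TP, cm.TP + cm.FP)
    if math.isnan(sens) or math.isnan(ppv) or sens == 0 or ppv == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * sens * ppv / (sens + ppv)
    return PerformanceReport(
        accuracy=(cm.TP + cm.TN) / cm.N,
        sensitivity=sens,
        specificity=_ratio(cm.TN, cm.TN + cm.FP),
        ppv=ppv,
        npv=_ratio(cm.TN, cm.TN + cm.FN),
        f1=f1,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def reconstruct_cm(
    n_pos: int, n_neg: int, sensitivity: float, specificity: float
) -> ConfusionMatrix:
    """Recover integer confusion counts from printed sensitivity/specificity.

    TP = round(sensitivity * n_pos) and TN = round(specificity * n_neg),
    rounding half-up; FN and FP are the complements.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ConfigurationError("sensitivity/specificity must lie in [0, 1]")
    if n_pos < 0 or n_neg < 0:
        raise ConfigurationError("class sizes must be non-negative")
    tp = _round_half_up(sensitivity * n_pos)
    tn = _round_half_up(specificity * n_neg)
    return ConfusionMatrix(TP=tp, FP=n_neg - tn, FN=n_pos - tp, TN=tn)
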