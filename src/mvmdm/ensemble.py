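"""Max-voting fusion of the route predictions and the metric suite.

The ensemble prediction is the strict majority of the three route votes
(ties are impossible with three binary voters; for even ensembles the mean
probability against the threshold breaks ties, as a documented extension).
The positive class is the disease class (label 1), which fixes the
sensitivity/precision conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "VoteTriple",
    "ConfusionMatrix",
    "MetricsReport",
    "max_vote",
    "majority_vote",
    "confusion_matrix",
    "compute_metrics",
]


@dataclass(frozen=True)
class VoteTriple:
    """Ordered binary votes from the (1D, 2D, 3D) routes."""

    votes: tuple[int, int, int]
    probabilities: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.votes) != 3:
            raise ValueError(f"expected exactly 3 votes, got {len(self.votes)}")
        if any(v not in (0, 1) for v in self.votes):
            raise ValueError(f"votes must be binary, got {self.votes}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with the disease class (1) positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def N(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The five derived metrics, as percentages at full precision.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


def max_vote(
    votes: Sequence[int] | VoteTriple,
    probabilities: Sequence[float] | None = None,
    threshold: float = 0.5,
) -> int:
    """Majority vote over binary predictions.

    With three voters (the standard ensemble) the majority is always strict.
    For an even number of voters a tie falls back to comparing the mean
    probability against the threshold, which requires probabilities.
    """
    if isinstance(votes, VoteTriple):
        probabilities = votes.probabilities if probabilities is None else probabilities
        votes = votes.votes
    votes = list(votes)
    if not votes:
        raise ValueError("at least one vote is required")
    if any(v not in (0, 1) for v in votes):
        raise ValueError(f"votes must be binary, got {votes}")
    ones = sum(votes)
    if 2 * ones > len(votes):
        return 1
    if 2 * ones < len(votes):
        return 0
    if probabilities is None:
        raise ValueError("tied vote with no probabilities to break the tie")
    return int(float(np.mean(probabilities)) >= threshold)


def majority_vote(predictions: np.ndarray) -> np.ndarray:
    """Row-wise majority over a (n_models, n_samples) binary array."""
    predictions = np.asarray(predictions)
    if predictions.ndim != 2:
        raise ValueError("expected (n_models, n_samples)")
    if predictions.shape[0] % 2 == 0:
        raise ValueError("use max_vote with probabilities for even ensembles")
    return (predictions.sum(axis=0) * 2 > predictions.shape[0]).astype(int)


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """TP/TN/FP/FN counts; the counts partition the sample."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1 or len(y_true) == 0:
        raise ValueError("y_true and y_pred must be equal-length non-empty 1D vectors")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must contain only 0/1 entries")
    return ConfusionMatrix(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, sensitivity, specificity and F1 as percentages."""
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    precision = _ratio(cm.TP, cm.TP + cm.FP)
    sensitivity = _ratio(cm.TP, cm.TP + cm.FN)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=_ratio(cm.TP + cm.TN, cm.N),
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(cm.TN, cm.TN + cm.FP),
        f1=f1,
    )
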