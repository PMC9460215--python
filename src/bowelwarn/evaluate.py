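"""Segment prediction and confusion-matrix diagnostics.

The positive class is label 1 (defecation tendency).  Rates follow the
standard definitions

    Accuracy = (TP + TN) / (TP + FP + TN + FN)
    Spc      = TN / (TN + FP)          (specificity)
    Sen      = TP / (TP + FN)          (sensitivity)

computed with exact rational arithmetic and rounded half-up to one decimal
in percent only for display.  Multi-task reports take the unweighted
(macro) mean of per-task rates, plus the mean of the raw counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import forward_classifier

__all__ = ["ConfusionCounts", "MetricsReport", "predict_segments",
           "confusion", "accuracy", "specificity", "sensitivity",
           "aggregate_tasks", "warning_decision", "display_percent"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with class 1 (defecation tendency) as positive."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _rate(num: int, den: int, name: str) -> Optional[Fraction]:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator")
        return None
    return Fraction(num, den)


def accuracy(c: ConfusionCounts) -> Optional[Fraction]:
    """(TP + TN) / total, or None (with a warning) on empty input."""
    return _rate(c.TP + c.TN, c.total, "accuracy")


def specificity(c: ConfusionCounts) -> Optional[Fraction]:
    """TN / (TN + FP): the rate at which quiescent segments are kept quiet."""
    return _rate(c.TN, c.TN + c.FP, "specificity")


def sensitivity(c: ConfusionCounts) -> Optional[Fraction]:
    """TP / (TP + FN): the rate at which pre-defecation segments are caught."""
    return _rate(c.TP, c.TP + c.FN, "sensitivity")


def display_percent(rate, decimals: int = 1) -> float:
    """Round-half-up display convention, e.g. Fraction(129,140) -> 92.1."""
    if rate is None:
        return math.nan
    exact = Decimal(rate.numerator) * 100 / Decimal(rate.denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def predict_segments(classifier, frames: np.ndarray) -> np.ndarray:
    """Predicted real-class labels {0, 1} for a batch of spectral frames.

    Argmax over the K + 1 outputs; when the fake class wins on real data
    (possible early in training) the prediction falls back to the larger of
    the two real-class probabilities, ties resolved to class 0 (the lowest
    index).
    """
    probs = np.atleast_2d(forward_classifier(classifier, frames))
    return predictions_from_probabilities(probs)


def predictions_from_probabilities(probs: np.ndarray) -> np.ndarray:
    """The argmax / fake-exclusion / lowest-index tie-break rule on
    pre-computed (B, K+1) probability rows."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    real = probs[:, :-1]
    # argmax with lowest-index tie-break is numpy's argmax convention
    preds = np.argmax(real, axis=1)
    return preds.astype(np.int64)


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN over paired label sequences in {0, 1}."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    if not (np.isin(predicted, (0, 1)).all() and np.isin(truth, (0, 1)).all()):
        raise ValueError("labels must be 0 or 1")
    return ConfusionCounts(
        TP=int(np.sum((predicted == 1) & (truth == 1))),
        TN=int(np.sum((predicted == 0) & (truth == 0))),
        FP=int(np.sum((predicted == 1) & (truth == 0))),
        FN=int(np.sum((predicted == 0) & (truth == 1))),
    )


@dataclass
class MetricsReport:
    """Per-task confusion counts and rates plus macro averages."""

    task_names: list[str]
    counts: list[ConfusionCounts]
    accuracies: list[Optional[Fraction]]
    specificities: list[Optional[Fraction]]
    sensitivities: list[Optional[Fraction]]
    macro_accuracy: Optional[Fraction]
    macro_specificity: Optional[Fraction]
    macro_sensitivity: Optional[Fraction]
    mean_counts: tuple[Fraction, Fraction, Fraction, Fraction]

    def to_dataframe(self) -> pd.DataFrame:
        """Standard multi-task results layout: one row
        per task, rates shown as round-half-up percentages, plus an Average
        row of macro means."""
        rows = []
        for name, c, a, sp, se in zip(self.task_names, self.counts,
                                      self.accuracies, self.specificities,
                                      self.sensitivities):
            rows.append({"task": name, "TP": c.TP, "TN": c.TN, "FP": c.FP,
                         "FN": c.FN, "accuracy_pct": display_percent(a),
                         "specificity_pct": display_percent(sp),
                         "sensitivity_pct": display_percent(se)})
        mc = [round(float(v), 1) for v in self.mean_counts]
        rows.append({"task": "Average",
                     "TP": mc[0], "TN": mc[1], "FP": mc[2], "FN": mc[3],
                     "accuracy_pct": display_percent(self.macro_accuracy),
                     "specificity_pct": display_percent(self.macro_specificity),
                     "sensitivity_pct": display_percent(self.macro_sensitivity)})
        return pd.DataFrame(rows)


def _macro(values: list[Optional[Fraction]]) -> Optional[Fraction]:
    defined = [v for v in values if v is not None]
    if not defined:
        return None
    return sum(defined, Fraction(0)) / len(defined)


def aggregate_tasks(counts: Sequence[ConfusionCounts],
                    task_names: Optional[Sequence[str]] = None) -> MetricsReport:
    """Per-task rates and their unweighted (macro) means across tasks."""
    counts = list(counts)
    if not counts:
        raise ValueError("need at least one task")
    if task_names is None:
        task_names = [chr(ord("A") + i) for i in range(len(counts))]
    accs = [accuracy(c) for c in counts]
    spcs = [specificity(c) for c in counts]
    sens = [sensitivity(c) for c in counts]
    n = Fraction(len(counts))
    mean_counts = (sum(Fraction(c.TP) for c in counts) / n,
                   sum(Fraction(c.TN) for c in counts) / n,
                   sum(Fraction(c.FP) for c in counts) / n,
                   sum(Fraction(c.FN) for c in counts) / n)
    return MetricsReport(list(task_names), counts, accs, spcs, sens,
                         _macro(accs), _macro(spcs), _macro(sens),
                         mean_counts)


def warning_decision(segment_predictions: Sequence[int],
                     threshold_fraction: float = 0.5) -> bool:
    """Recording-level pre-warning: True (warn) iff the fraction of
    segments predicted as class 1 is >= ``threshold_fraction``.

    With 24 segments per recording, a threshold of 1/24 recovers
    warn-on-any-segment behaviour.
    """
    preds = np.asarray(segment_predictions)
    if preds.size == 0:
        raise ValueError("need at least one segment prediction")
    return bool(np.mean(preds == 1) >= threshold_fraction)
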