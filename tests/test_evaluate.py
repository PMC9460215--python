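"""Confusion-matrix arithmetic, prediction rules, aggregation, warnings."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bowelwarn import evaluate
from bowelwarn.evaluate import (ConfusionCounts, accuracy, aggregate_tasks,
                                confusion, display_percent,
                                predictions_from_probabilities, sensitivity,
                                specificity, warning_decision)

# The six evaluation tasks' confusion counts (200 segments, 60 positives)
TASK_COUNTS = [
    ConfusionCounts(TP=55, TN=129, FP=11, FN=5),
    ConfusionCounts(TP=56, TN=136, FP=4, FN=4),
    ConfusionCounts(TP=53, TN=134, FP=6, FN=7),
    ConfusionCounts(TP=56, TN=129, FP=11, FN=4),
    ConfusionCounts(TP=55, TN=132, FP=8, FN=5),
    ConfusionCounts(TP=59, TN=139, FP=1, FN=1),
]


class TestPredictionRule:
    @pytest.mark.parametrize("probs,expected", [
        ([0.7, 0.2, 0.1], 0),          # plain argmax
        ([0.2, 0.3, 0.5], 1),          # fake wins -> best real class
        ([0.25, 0.25, 0.5], 0),        # tie between real classes -> 0
        ([0.1, 0.85, 0.05], 1),
    ])
    def test_fake_exclusion_and_tie_break(self, probs, expected):
        assert predictions_from_probabilities([probs])[0] == expected


class TestConfusion:
    def test_perfect_prediction(self):
        truth = [1] * 60 + [0] * 140
        c = confusion(truth, truth)
        assert (c.TP, c.TN, c.FP, c.FN) == (60, 140, 0, 0)

    def test_task_a_outcome_pattern(self):
        """A prediction pattern with 5 missed positives and 11 false alarms
        on the 200/60 composition yields TP=55, TN=129, FP=11, FN=5."""
        truth = np.array([1] * 60 + [0] * 140)
        pred = truth.copy()
        pred[:5] = 0       # 5 missed positives
        pred[60:71] = 1    # 11 false alarms
        c = confusion(pred, truth)
        assert (c.TP, c.TN, c.FP, c.FN) == (55, 129, 11, 5)

    def test_all_negative_predictor(self):
        truth = np.array([1] * 60 + [0] * 140)
        c = confusion(np.zeros_like(truth), truth)
        assert (c.TP, c.TN, c.FP, c.FN) == (0, 140, 0, 60)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 2], [0, 1])


class TestRates:
    def test_accuracy_of_task_a(self):
        assert accuracy(TASK_COUNTS[0]) == Fraction(184, 200)
        assert display_percent(accuracy(TASK_COUNTS[0])) == 92.0

    def test_specificity_example(self):
        assert specificity(TASK_COUNTS[1]) == Fraction(136, 140)
        assert display_percent(specificity(TASK_COUNTS[1])) == 97.1

    def test_sensitivity_example(self):
        assert sensitivity(TASK_COUNTS[5]) == Fraction(59, 60)
        assert display_percent(sensitivity(TASK_COUNTS[5])) == 98.3

    def test_empty_counts_are_undefined(self):
        c = ConfusionCounts(0, 0, 0, 0)
        with pytest.warns(UserWarning, match="undefined"):
            assert accuracy(c) is None
        assert math.isnan(display_percent(None))

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.integers(0, 500)] * 4))
    def test_rates_bounded_and_consistent(self, counts):
        import warnings as _warnings
        c = ConfusionCounts(*counts)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", UserWarning)
            acc, spc, sen = accuracy(c), specificity(c), sensitivity(c)
        for rate in (acc, spc, sen):
            if rate is not None:
                assert 0 <= rate <= 1
        if acc is not None and spc is not None and sen is not None:
            # accuracy decomposes into the class-conditional rates
            assert acc == (sen * (c.TP + c.FN) + spc * (c.TN + c.FP)) \
                / c.total

    def test_matches_sklearn_on_random_labels(self):
        from sklearn.metrics import accuracy_score, confusion_matrix
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 2, 300)
        pred = rng.integers(0, 2, 300)
        c = confusion(pred, truth)
        tn, fp, fn, tp = confusion_matrix(truth, pred).ravel()
        assert (c.TP, c.TN, c.FP, c.FN) == (tp, tn, fp, fn)
        assert float(accuracy(c)) == pytest.approx(
            accuracy_score(truth, pred))


class TestAggregation:
    def test_six_task_macro_averages(self):
        report = aggregate_tasks(TASK_COUNTS)
        assert display_percent(report.macro_accuracy) == 94.4
        assert display_percent(report.macro_specificity) == 95.1
        # exact macro-mean sensitivity is 334/360 (92.8 at one decimal)
        assert report.macro_sensitivity == Fraction(334, 360)
        assert display_percent(report.macro_sensitivity) == 92.8

    def test_mean_counts(self):
        report = aggregate_tasks(TASK_COUNTS)
        assert report.mean_counts == (Fraction(334, 6), Fraction(799, 6),
                                      Fraction(41, 6), Fraction(26, 6))

    def test_single_task_average_is_itself(self):
        report = aggregate_tasks([TASK_COUNTS[0]])
        assert report.macro_accuracy == accuracy(TASK_COUNTS[0])
        assert report.macro_specificity == specificity(TASK_COUNTS[0])

    def test_identical_tasks_average_unchanged(self):
        report = aggregate_tasks([TASK_COUNTS[2]] * 4)
        assert report.macro_accuracy == accuracy(TASK_COUNTS[2])

    def test_dataframe_layout(self):
        frame = aggregate_tasks(TASK_COUNTS).to_dataframe()
        assert list(frame["task"]) == ["A", "B", "C", "D", "E", "F",
                                       "Average"]
        assert frame.iloc[-1]["accuracy_pct"] == 94.4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_tasks([])


class TestWarningDecision:
    def test_majority_triggers_warning(self):
        assert warning_decision([1] * 13 + [0] * 11, 0.5) is True

    def test_quiet_recording_no_warning(self):
        assert warning_decision([0] * 24, 0.5) is False

    def test_any_segment_threshold(self):
        preds = [0] * 23 + [1]
        assert warning_decision(preds, 1 / 24) is True
        assert warning_decision(preds, 0.5) is False

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            warning_decision([])
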