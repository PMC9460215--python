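"""Confusion-count arithmetic on a multi-task evaluation.

Six hypothetical test sets of 200 segments (60 positive) are summarised
the way the method's results are reported: per-task accuracy, specificity
and sensitivity plus an unweighted (macro) Average row.
"""

from bowelwarn.evaluate import ConfusionCounts, aggregate_tasks

counts = [
    ConfusionCounts(TP=55, TN=129, FP=11, FN=5),
    ConfusionCounts(TP=56, TN=136, FP=4, FN=4),
    ConfusionCounts(TP=53, TN=134, FP=6, FN=7),
    ConfusionCounts(TP=56, TN=129, FP=11, FN=4),
    ConfusionCounts(TP=55, TN=132, FP=8, FN=5),
    ConfusionCounts(TP=59, TN=139, FP=1, FN=1),
]
report = aggregate_tasks(counts)
print(report.to_dataframe().to_string(index=False))
# The Average row is the unweighted mean of the per-task percentages
# (macro average), printed round-half-up to one decimal.
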