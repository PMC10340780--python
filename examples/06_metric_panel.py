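"""The metric panel on a hand-built confusion matrix.

The Clopper-Pearson interval is the exact binomial CI (Beta-quantile
form); undefined ratios are reported as absent-with-reason rather than
zero-filled.
"""

from pslearn import ConfusionMatrix, auc, clopper_pearson, metrics_from_confusion

rep = metrics_from_confusion(ConfusionMatrix(tp=8, fn=2, fp=1, tn=9))
print(rep.to_table())

lo, hi = clopper_pearson(0, 10)
print(f"\nexact 95% CI for 0 successes in 10 trials: ({lo:.4f}, {hi:.4f})")

print(f"AUC for scores (0.1, 0.4, 0.35, 0.8) with labels (0, 0, 1, 1): "
      f"{auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]):.2f}")

degenerate = metrics_from_confusion(ConfusionMatrix(tp=0, fp=0, tn=9, fn=1))
print(f"precision with no positive predictions: {degenerate.precision.reason}")
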