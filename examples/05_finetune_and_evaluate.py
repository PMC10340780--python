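"""Fine-tune a classifier from a pretrained encoder and evaluate it.

Prints the full metric panel — accuracy, sensitivity, specificity and
precision with exact 95% Clopper-Pearson intervals, plus F1 and AUC —
on a held-out phantom cohort.
"""

from pslearn import evaluate_classifier, finetune_classifier, generate_cohort
from pslearn.benchmarks import desk_finetune_config, easy_phantoms

train, _ = generate_cohort(easy_phantoms(), 30, seed=10)
val, _ = generate_cohort(easy_phantoms(), 25, seed=11)

bundle, log = finetune_classifier(None, train, desk_finetune_config(0, epochs=40))
report = evaluate_classifier(bundle, val)
print("classifier trained from random initialization on 60 labeled slices:")
print(report.to_table())
cm = report.confusion
print(f"confusion: TP={cm.tp} FP={cm.fp} TN={cm.tn} FN={cm.fn} (positive = {cm.positive})")
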