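"""A miniature labeled-data-fraction experiment.

Runs fine-tuning at two labeled fractions, with and without pretext
pretraining, under otherwise identical conditions, and prints the long-
format results table. At small fractions the pretrained encoder should
hold up better. (This is a fast demo; the full benchmark uses more seeds
and fractions — see scripts/acceptance.py.)
"""

from pslearn import (
    FractionExperimentSpec,
    TrainConfig,
    build_ps_dataset,
    generate_cohort,
    run_fraction_experiment,
)
from pslearn.benchmarks import desk_insertion, desk_lesions, standard_phantoms

train, _ = generate_cohort(standard_phantoms(), 20, seed=30)
val, _ = generate_cohort(standard_phantoms(), 15, seed=31)
ps = build_ps_dataset([ls.slice for ls in train], desk_lesions(), desk_insertion(),
                      n_per_slice=1, negative_fraction=0.25, seed=32)

spec = FractionExperimentSpec(fractions=(0.25, 1.0), seeds=(0,),
                              metrics=("accuracy", "sensitivity", "auc"))
results = run_fraction_experiment(
    spec, train, val, ps,
    TrainConfig(epochs=8, batch_size=8, seed=0),
    TrainConfig(epochs=25, batch_size=4, lr=1e-3, seed=0),
)
table = results.pivot_table(index=["fraction", "condition"], columns="metric", values="value")
print(table.round(3).to_string())
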