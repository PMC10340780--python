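"""Pretrain a segmenter on self-labeled pseudo-lesion examples.

No human annotation is involved: the masks come from the insertion step.
The per-epoch log shows the compound BCE + soft-Dice loss falling and the
held-out Dice rising; the encoder is then exportable for transfer.
"""

import numpy as np

from pslearn import TrainConfig, build_ps_dataset, export_encoder, generate_cohort, pretrain_segmenter
from pslearn.benchmarks import desk_insertion, desk_lesions, easy_phantoms
from pslearn.nn.models import build_segmenter

cohort, _ = generate_cohort(easy_phantoms(), 25, seed=3)
examples = build_ps_dataset([ls.slice for ls in cohort], desk_lesions(), desk_insertion(),
                            n_per_slice=2, negative_fraction=0.25, seed=4)
print(f"{len(examples)} pretext examples "
      f"({sum(1 for e in examples if not e.mask.any())} clean negatives)")

bundle = build_segmenter("tinyunet-w8-l3", seed=0)
bundle, log = pretrain_segmenter(bundle, examples, TrainConfig(epochs=20, batch_size=8, seed=0, patience=6))
print(log.to_string(index=False, float_format="%.4f"))

state = export_encoder(bundle)
n_params = sum(v.size for v in state.params.values())
print(f"\nexported encoder '{state.arch_id}' with {n_params} parameters for transfer")
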