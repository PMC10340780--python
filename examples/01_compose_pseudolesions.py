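"""Compose pseudo-lesions: random unions of overlapping simple shapes.

Each lesion is a single connected binary blob built from 2-4 circles,
rotated ellipses and convex polygons, boundary-smoothed by a morphological
closing. The printed effective diameter is the diameter of the equal-area
circle, bounded by the configured [d_min, d_max].
"""

import numpy as np

from pslearn import LesionConfig, compose_pseudo_lesion
from pslearn.imgio import mask_to_rle

config = LesionConfig(size_range=(3.0, 7.0), count_range=(2, 4),
                      d_min=5.0, d_max=16.0, smoothing_radius=1)

for seed in range(5):
    lesion = compose_pseudo_lesion(np.random.default_rng(seed), config)
    kinds = ",".join(p.kind for p in lesion.recipe)
    print(f"seed {seed}: {len(lesion.recipe)} primitives ({kinds}), "
          f"area {lesion.area} px, effective diameter {lesion.effective_diameter:.1f} px")

lesion = compose_pseudo_lesion(np.random.default_rng(0), config)
print("\nrun-length encoding of the first mask (text-portable fixture format):")
print(mask_to_rle(lesion.mask)[:100] + "...")
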