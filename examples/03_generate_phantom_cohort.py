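"""Generate a labeled phantom cohort and inspect its manifest.

Cancer slices carry a hypodense tumor inside the enhanced pancreas region;
the stage proxy records the tumor's effective diameter in mm (a T-stage
stand-in: <= 20 mm is T1-like).
"""

from pslearn import generate_cohort
from pslearn.benchmarks import standard_phantoms

cohort, manifest = generate_cohort(standard_phantoms(), {"normal": 10, "cancer": 10}, seed=1)

print(manifest.to_string(index=False))
sizes = manifest.dropna(subset=["stage_proxy_mm"])["stage_proxy_mm"]
print(f"\n{len(cohort)} slices; tumor diameters {sizes.min():.1f}-{sizes.max():.1f} mm "
      f"(median {sizes.median():.1f} mm)")
t1 = (sizes <= 20).sum()
print(f"T1-like (<=20 mm): {t1} of {len(sizes)} tumors")
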