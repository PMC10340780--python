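"""Canonical desk-scale benchmark conditions.

Two fixed phantom regimes drive the package's own experiments and tests:

- **easy**: noiseless phantoms with a strongly hypodense tumor — used to
  check that the pretext task is learnable and that Grad-CAM localizes.
- **standard**: moderate correlated noise (15 HU, typical of abdominal CT)
  and a moderately hypodense tumor — the regime for the labeled-fraction
  experiment, where the pretraining benefit is measured.

Phantoms here are 64x64 at 2 mm spacing (an abdominal field of view scaled
down fourfold from 512-px CT), which keeps a full fraction experiment
within minutes on one CPU.  The values are fixed study conditions, not
tuning knobs; anything else should be configured explicitly.
"""

from __future__ import annotations

from .finetune import FractionExperimentSpec
from .insertion import InsertionModel
from .phantoms import PhantomConfig
from .shapes import LesionConfig
from .training import TrainConfig

CANVAS = 64


def easy_phantoms() -> PhantomConfig:
    return PhantomConfig(
        canvas=(CANVAS, CANVAS),
        spacing=(2.0, 2.0),
        pancreas_radius_frac=(0.18, 0.24),
        tumor_diameter_range=(4.0, 12.0),
        tumor_delta_range=(-70.0, -50.0),
        tumor_feather_sigma=1.0,
        noise_sd=0.0,
    )


def standard_phantoms() -> PhantomConfig:
    return PhantomConfig(
        canvas=(CANVAS, CANVAS),
        spacing=(2.0, 2.0),
        pancreas_radius_frac=(0.18, 0.24),
        tumor_diameter_range=(4.0, 12.0),
        tumor_delta_range=(-60.0, -40.0),
        tumor_feather_sigma=1.0,
        noise_sd=15.0,
        noise_corr_scale=1.0,
    )


def desk_lesions() -> LesionConfig:
    return LesionConfig(
        size_range=(3.0, 7.0),
        count_range=(2, 4),
        d_min=5.0,
        d_max=16.0,
        smoothing_radius=1,
    )


def desk_insertion() -> InsertionModel:
    return InsertionModel(delta_range=(-60.0, -20.0), feather_sigma=1.5,
                          placement="region-constrained")


def desk_pretext_config(seed: int = 0, epochs: int = 20) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=8, lr=3e-3, seed=seed, patience=6)


def desk_finetune_config(seed: int = 0, epochs: int = 60) -> TrainConfig:
    # small batches + many epochs: the interesting regime is ~10 labeled
    # slices, where step count, not data passes, limits convergence
    return TrainConfig(epochs=epochs, batch_size=4, lr=1e-3, seed=seed)


def desk_experiment_spec() -> FractionExperimentSpec:
    return FractionExperimentSpec(fractions=(0.10, 0.25, 0.50, 0.75, 1.0), seeds=(0, 1, 2))
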