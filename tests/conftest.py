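import numpy as np
import pytest

from pslearn.phantoms import PhantomConfig, generate_cohort
from pslearn.shapes import LesionConfig


@pytest.fixture(scope="session")
def tiny_phantom_cfg() -> PhantomConfig:
    """32-px noiseless phantoms: fast enough for per-test generation."""
    return PhantomConfig(
        canvas=(32, 32),
        spacing=(4.0, 4.0),
        pancreas_radius_frac=(0.22, 0.28),
        tumor_diameter_range=(4.0, 8.0),
        tumor_delta_range=(-70.0, -50.0),
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_phantom_cfg):
    cohort, manifest = generate_cohort(tiny_phantom_cfg, 6, seed=42)
    return cohort, manifest


@pytest.fixture()
def tiny_lesion_cfg() -> LesionConfig:
    return LesionConfig(size_range=(2.0, 4.0), count_range=(2, 3), d_min=3.0, d_max=10.0,
                        smoothing_radius=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
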