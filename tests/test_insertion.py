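"""Lesion insertion: placement admissibility, feathering oracle, dataset contracts."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.stats import chisquare

from pslearn.errors import ConfigurationError, PlacementError
from pslearn.insertion import (
    ImageSlice,
    InsertionModel,
    admissible_centers,
    build_ps_dataset,
    choose_placement,
    insert_lesion,
)
from pslearn.shapes import LesionConfig, compose_pseudo_lesion


def brute_gaussian_blur(mask: np.ndarray, sigma: float) -> np.ndarray:
    """Independent oracle: explicit discrete Gaussian convolution, zero padding.

    Kernel radius matches the implementation's truncation (4 sigma); the
    kernel is the separable outer product of normalized sampled Gaussians.
    """
    radius = int(4.0 * sigma + 0.5)
    xs = np.arange(-radius, radius + 1)
    k1 = np.exp(-(xs**2) / (2.0 * sigma**2))
    k1 /= k1.sum()
    k2 = np.outer(k1, k1)
    src = np.pad(mask.astype(np.float64), radius)
    out = np.zeros_like(mask, dtype=np.float64)
    h, w = mask.shape
    for i, di in enumerate(range(-radius, radius + 1)):
        for j, dj in enumerate(range(-radius, radius + 1)):
            out += k2[i, j] * src[radius + di : radius + di + h, radius + dj : radius + dj + w]
    return out


@pytest.fixture()
def lesion(tiny_lesion_cfg):
    return compose_pseudo_lesion(np.random.default_rng(3), tiny_lesion_cfg)


def flat_slice(value=100.0, shape=(64, 64), region=None):
    return ImageSlice(np.full(shape, value), (1.0, 1.0), region_mask=region)


class TestPlacement:
    def test_region_constrained_centers_keep_lesion_inside_block(self, lesion):
        region = np.zeros((128, 128), dtype=bool)
        region[30:90, 40:100] = True
        slc = flat_slice(shape=(128, 128), region=region)
        model = InsertionModel(placement="region-constrained")
        rng = np.random.default_rng(0)
        h, w = lesion.mask.shape
        for _ in range(200):
            r, c = choose_placement(slc, lesion, model, rng)
            top, left = r - h // 2, c - w // 2
            placed = np.zeros_like(region)
            placed[top : top + h, left : left + w] = lesion.mask
            assert not (placed & ~region).any()

    def test_oversized_lesion_raises(self, tiny_lesion_cfg):
        lesion = compose_pseudo_lesion(np.random.default_rng(1), tiny_lesion_cfg)
        slc = flat_slice(shape=(4, 4))
        with pytest.raises(PlacementError):
            choose_placement(slc, lesion, InsertionModel(placement="anywhere-in-body"),
                             np.random.default_rng(0))

    def test_anywhere_in_body_coverage_is_uniform(self, lesion):
        # body mask covers the whole slice; admissible centers form a rectangle
        slc = flat_slice(shape=(64, 64))
        model = InsertionModel(placement="anywhere-in-body")
        centers = admissible_centers(slc, lesion, model)
        rng = np.random.default_rng(7)
        draws = np.array([choose_placement(slc, lesion, model, rng) for _ in range(4000)])
        # occupancy over a 4x4 grid, expected counts proportional to the
        # admissible-center count in each cell
        edges_r = np.linspace(centers[:, 0].min(), centers[:, 0].max() + 1, 5)
        edges_c = np.linspace(centers[:, 1].min(), centers[:, 1].max() + 1, 5)
        obs, _, _ = np.histogram2d(draws[:, 0], draws[:, 1], bins=(edges_r, edges_c))
        exp, _, _ = np.histogram2d(centers[:, 0], centers[:, 1], bins=(edges_r, edges_c))
        exp = exp / exp.sum() * len(draws)
        stat, p = chisquare(obs.ravel(), exp.ravel())
        assert p > 0.01


class TestInsert:
    def test_zero_delta_leaves_image_bit_identical(self, lesion):
        slc = flat_slice()
        model = InsertionModel(delta_range=(0.0, 0.0), feather_sigma=1.5,
                               placement="anywhere-in-body")
        rng = np.random.default_rng(2)
        center = choose_placement(slc, lesion, model, rng)
        ex = insert_lesion(slc, lesion, center, model, rng)
        assert np.array_equal(ex.image.pixels, slc.pixels)
        assert ex.mask.sum() == lesion.area

    def test_hard_edge_is_piecewise_constant(self, lesion):
        slc = flat_slice(100.0)
        model = InsertionModel(delta_range=(-40.0, -40.0), feather_sigma=0.0,
                               placement="anywhere-in-body")
        rng = np.random.default_rng(2)
        center = choose_placement(slc, lesion, model, rng)
        ex = insert_lesion(slc, lesion, center, model, rng)
        assert np.all(ex.image.pixels[ex.mask] == 60.0)
        assert np.all(ex.image.pixels[~ex.mask] == 100.0)

    def test_feathered_insertion_matches_convolution_oracle(self, lesion):
        slc = flat_slice(100.0)
        sigma = 2.0
        model = InsertionModel(delta_range=(-40.0, -40.0), feather_sigma=sigma,
                               placement="anywhere-in-body")
        rng = np.random.default_rng(4)
        center = choose_placement(slc, lesion, model, rng)
        ex = insert_lesion(slc, lesion, center, model, rng)
        expected = 100.0 - 40.0 * brute_gaussian_blur(ex.mask, sigma)
        assert np.max(np.abs(ex.image.pixels - expected)) < 1e-6

    def test_negative_delta_darkens_mask_interior(self, lesion):
        slc = flat_slice(100.0)
        model = InsertionModel(delta_range=(-60.0, -20.0), feather_sigma=1.5,
                               placement="anywhere-in-body")
        rng = np.random.default_rng(5)
        center = choose_placement(slc, lesion, model, rng)
        ex = insert_lesion(slc, lesion, center, model, rng)
        assert ex.image.pixels[ex.mask].mean() < slc.pixels[ex.mask].mean()

    def test_out_of_bounds_center_raises(self, lesion):
        slc = flat_slice()
        model = InsertionModel(placement="anywhere-in-body")
        with pytest.raises(PlacementError):
            insert_lesion(slc, lesion, (0, 0), model, np.random.default_rng(0))


class TestBuildDataset:
    def make_slices(self, n=5):
        region = np.zeros((48, 48), dtype=bool)
        region[10:38, 10:38] = True
        return [flat_slice(100.0 + i, (48, 48), region.copy()) for i in range(n)]

    def test_exact_negative_fraction(self, tiny_lesion_cfg):
        examples = build_ps_dataset(self.make_slices(5), tiny_lesion_cfg, InsertionModel(),
                                    n_per_slice=20, negative_fraction=0.5, seed=9)
        n_empty = sum(1 for ex in examples if not ex.mask.any())
        assert len(examples) == 100 and n_empty == 50

    def test_same_seed_identical_dataset(self, tiny_lesion_cfg):
        a = build_ps_dataset(self.make_slices(3), tiny_lesion_cfg, InsertionModel(),
                             n_per_slice=4, negative_fraction=0.25, seed=13)
        b = build_ps_dataset(self.make_slices(3), tiny_lesion_cfg, InsertionModel(),
                             n_per_slice=4, negative_fraction=0.25, seed=13)
        for ea, eb in zip(a, b):
            assert np.array_equal(ea.image.pixels, eb.image.pixels)
            assert np.array_equal(ea.mask, eb.mask)

    def test_positives_bitexact_outside_feather_band(self, tiny_lesion_cfg):
        slices = self.make_slices(4)
        model = InsertionModel(feather_sigma=1.5)
        examples = build_ps_dataset(slices, tiny_lesion_cfg, model,
                                    n_per_slice=5, negative_fraction=0.2, seed=21)
        radius = int(4.0 * model.feather_sigma + 0.5)
        footprint = np.ones((2 * radius + 1, 2 * radius + 1), dtype=bool)
        for i, ex in enumerate(examples):
            src = slices[i // 5].pixels
            if not ex.mask.any():
                assert np.array_equal(ex.image.pixels, src)
                continue
            band = ndimage.binary_dilation(ex.mask, structure=footprint)
            assert np.array_equal(ex.image.pixels[~band], src[~band])

    def test_invalid_arguments(self, tiny_lesion_cfg):
        with pytest.raises(ConfigurationError):
            build_ps_dataset([], tiny_lesion_cfg, InsertionModel())
        with pytest.raises(ConfigurationError):
            build_ps_dataset(self.make_slices(1), tiny_lesion_cfg, InsertionModel(),
                             negative_fraction=1.0)
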