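"""Pseudo-lesion shape synthesis: rasterization oracles and composition invariants."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from pslearn.errors import ConfigurationError, GenerationError
from pslearn.shapes import (
    STRUCT8,
    LesionConfig,
    Primitive,
    compose_pseudo_lesion,
    rasterize,
    sample_primitive,
    union_mask,
)


def brute_circle_pixels(center, radius, shape):
    """Independent oracle: count integer points with (r-cr)^2+(c-cc)^2 <= R^2."""
    out = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            if (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2:
                out[r, c] = True
    return out


class TestRasterize:
    def test_circle_r3_center_of_9x9_sets_29_pixels(self):
        p = Primitive("circle", (4.0, 4.0), {"radius": 3.0})
        mask = rasterize(p, (9, 9))
        assert mask.sum() == 29
        assert np.array_equal(mask, brute_circle_pixels((4, 4), 3, (9, 9)))

    @pytest.mark.parametrize("radius", [1.0, 2.5, 3.0, 5.7])
    @pytest.mark.parametrize("center", [(7.0, 7.0), (6.5, 7.25)])
    def test_circle_matches_brute_force(self, radius, center):
        p = Primitive("circle", center, {"radius": radius})
        assert np.array_equal(rasterize(p, (15, 15)), brute_circle_pixels(center, radius, (15, 15)))

    def test_huge_circle_covers_canvas(self):
        p = Primitive("circle", (4.0, 4.0), {"radius": 1000.0})
        assert rasterize(p, (9, 9)).all()

    @pytest.mark.parametrize("rotation", [0.0, 0.3, 1.2, np.pi / 2])
    def test_equal_axes_ellipse_is_a_circle(self, rotation):
        circle = Primitive("circle", (10.0, 10.0), {"radius": 4.0})
        ellipse = Primitive("ellipse", (10.0, 10.0), {"semi_axes": (4.0, 4.0)}, rotation=rotation)
        assert np.array_equal(rasterize(circle, (21, 21)), rasterize(ellipse, (21, 21)))

    def test_offcanvas_primitive_yields_empty_mask(self):
        p = Primitive("circle", (100.0, 100.0), {"radius": 2.0})
        assert rasterize(p, (9, 9)).sum() == 0

    def test_polygon_raster_is_nonempty_and_connected(self, rng):
        for _ in range(25):
            p = sample_primitive(rng, (3.0, 6.0), kinds=("convex-polygon",),
                                 center=(12.0, 12.0))
            mask = rasterize(p, (25, 25))
            assert mask.any()
            assert ndimage.label(mask, structure=STRUCT8)[1] == 1

    @given(radius=st.floats(1.0, 6.0), dr=st.floats(-0.5, 0.5), dc=st.floats(-0.5, 0.5))
    @settings(max_examples=30, deadline=None)
    def test_circle_area_property(self, radius, dr, dc):
        center = (8.0 + dr, 8.0 + dc)
        p = Primitive("circle", center, {"radius": radius})
        assert np.array_equal(
            rasterize(p, (17, 17)), brute_circle_pixels(center, radius, (17, 17))
        )


class TestSamplePrimitive:
    def test_degenerate_range_forces_radius(self, rng):
        p = sample_primitive(rng, (5.0, 5.0), kinds=("circle",))
        assert p.kind == "circle" and p.size["radius"] == 5.0

    def test_same_seed_same_primitive(self):
        a = sample_primitive(np.random.default_rng(7), (2.0, 9.0))
        b = sample_primitive(np.random.default_rng(7), (2.0, 9.0))
        assert a == b

    def test_effective_size_within_range(self, rng):
        for _ in range(200):
            p = sample_primitive(rng, (3.0, 8.0))
            assert 3.0 <= p.effective_size <= 8.0 + 1e-9

    def test_invalid_configs_raise(self, rng):
        with pytest.raises(ConfigurationError):
            sample_primitive(rng, (5.0, 2.0))
        with pytest.raises(ConfigurationError):
            sample_primitive(rng, (2.0, 5.0), kinds=())

    def test_kind_frequencies_match_probabilities(self):
        rng = np.random.default_rng(99)
        kinds = ("circle", "ellipse")
        n = 10_000
        draws = [sample_primitive(rng, (2.0, 5.0), kinds=kinds).kind for _ in range(n)]
        freq = draws.count("circle") / n
        se = np.sqrt(0.25 / n)  # binomial standard error at p=1/2
        assert abs(freq - 0.5) < 3 * se


class TestCompose:
    def test_two_overlapping_circles_union_oracle(self):
        a = Primitive("circle", (20.0, 20.0), {"radius": 5.0})
        b = Primitive("circle", (20.0, 26.0), {"radius": 5.0})
        mask = union_mask([a, b], (41, 41))
        brute = brute_circle_pixels((20, 20), 5, (41, 41)) | brute_circle_pixels(
            (20, 26), 5, (41, 41)
        )
        assert np.array_equal(mask, brute)

    def test_infeasible_diameter_bounds_raise(self, rng):
        cfg = LesionConfig(size_range=(1.0, 2.0), count_range=(2, 2),
                           d_min=40.0, d_max=40.0, max_retries=20)
        with pytest.raises(GenerationError):
            compose_pseudo_lesion(rng, cfg)

    def test_determinism_bit_identical(self, tiny_lesion_cfg):
        a = compose_pseudo_lesion(np.random.default_rng(5), tiny_lesion_cfg)
        b = compose_pseudo_lesion(np.random.default_rng(5), tiny_lesion_cfg)
        assert np.array_equal(a.mask, b.mask)
        assert a.recipe == b.recipe

    @pytest.mark.parametrize("smoothing", [0, 1, 2])
    def test_composition_invariants(self, smoothing):
        cfg = LesionConfig(size_range=(3.0, 7.0), count_range=(2, 4), d_min=5.0,
                           d_max=18.0, smoothing_radius=smoothing)
        for seed in range(60):
            lesion = compose_pseudo_lesion(np.random.default_rng(seed), cfg)
            assert len(lesion.recipe) >= 2
            assert ndimage.label(lesion.mask, structure=STRUCT8)[1] == 1
            assert cfg.d_min <= lesion.effective_diameter <= cfg.d_max
            area = lesion.mask.sum()
            assert np.isclose(lesion.effective_diameter, 2 * np.sqrt(area / np.pi))

    def test_smoothing_off_mask_is_exact_primitive_union(self):
        cfg = LesionConfig(size_range=(3.0, 7.0), count_range=(2, 4), d_min=5.0,
                           d_max=18.0, smoothing_radius=0)
        for seed in range(40):
            lesion = compose_pseudo_lesion(np.random.default_rng(seed), cfg)
            rebuilt = union_mask(lesion.recipe, lesion.mask.shape)
            assert np.array_equal(lesion.mask, rebuilt)

    def test_count_range_must_allow_plurality(self):
        with pytest.raises(ConfigurationError):
            LesionConfig(count_range=(1, 3))
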