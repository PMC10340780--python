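"""Phantom generator: geometry invariants, HU levels, size distribution."""

import numpy as np
import pytest
from scipy.stats import kstest

from pslearn.errors import ConfigurationError
from pslearn.phantoms import PhantomConfig, generate_cohort, generate_phantom, train_val_split


class TestGeneratePhantom:
    def test_noiseless_normal_phantom_is_piecewise_constant(self, tiny_phantom_cfg):
        ls = generate_phantom(np.random.default_rng(0), tiny_phantom_cfg, "normal")
        levels = set(np.unique(ls.slice.pixels))
        cfg = tiny_phantom_cfg
        assert levels == {cfg.hu_air, cfg.hu_body, cfg.hu_fat, cfg.hu_pancreas}

    def test_cancer_tumor_is_hypodense_vs_parenchyma(self, tiny_phantom_cfg):
        for seed in range(50):
            ls = generate_phantom(np.random.default_rng(seed), tiny_phantom_cfg, "cancer")
            region = ls.slice.region_mask
            inside = ls.slice.pixels[ls.tumor_mask].mean()
            outside = ls.slice.pixels[region & ~ls.tumor_mask].mean()
            assert inside < outside

    def test_geometry_nesting_tumor_in_pancreas_in_body(self, tiny_phantom_cfg):
        for seed in range(30):
            ls = generate_phantom(np.random.default_rng(seed), tiny_phantom_cfg, "cancer")
            body = ls.slice.pixels > tiny_phantom_cfg.hu_air
            assert not (ls.tumor_mask & ~ls.slice.region_mask).any()
            assert not (ls.slice.region_mask & ~body).any()

    def test_same_seed_identical_slice(self, tiny_phantom_cfg):
        a = generate_phantom(np.random.default_rng(6), tiny_phantom_cfg, "cancer")
        b = generate_phantom(np.random.default_rng(6), tiny_phantom_cfg, "cancer")
        assert np.array_equal(a.slice.pixels, b.slice.pixels)
        assert np.array_equal(a.tumor_mask, b.tumor_mask)
        assert a.stage_proxy == b.stage_proxy

    def test_benign_class_is_sharp_and_very_hypodense(self):
        cfg = PhantomConfig(canvas=(64, 64), spacing=(2.0, 2.0),
                            pancreas_radius_frac=(0.2, 0.26),
                            tumor_diameter_range=(4.0, 8.0), noise_sd=0.0,
                            class_scheme=("normal", "benign", "cancer"))
        ls = generate_phantom(np.random.default_rng(1), cfg, "benign")
        assert ls.label == "benign" and not ls.tumor_mask.any()
        assert (ls.slice.pixels == cfg.hu_cyst).any()

    def test_unknown_label_rejected(self, tiny_phantom_cfg):
        with pytest.raises(ConfigurationError):
            generate_phantom(np.random.default_rng(0), tiny_phantom_cfg, "benign")

    def test_infeasible_tumor_diameter_raises(self):
        cfg = PhantomConfig(canvas=(48, 48), pancreas_radius_frac=(0.12, 0.14),
                            tumor_diameter_range=(40.0, 40.0), noise_sd=0.0)
        with pytest.raises(Exception):
            generate_phantom(np.random.default_rng(0), cfg, "cancer")


class TestCohort:
    def test_counts_and_empty_masks(self, tiny_phantom_cfg):
        cohort, manifest = generate_cohort(tiny_phantom_cfg, {"normal": 7, "cancer": 5}, seed=1)
        assert len(cohort) == 12
        assert sum(1 for ls in cohort if not ls.tumor_mask.any()) == 7
        assert list(manifest.columns) == ["index", "label", "stage_proxy_mm", "seed"]

    def test_manifest_schema_stable_across_seeds(self, tiny_phantom_cfg):
        _, m1 = generate_cohort(tiny_phantom_cfg, 3, seed=1)
        _, m2 = generate_cohort(tiny_phantom_cfg, 3, seed=2)
        assert list(m1.columns) == list(m2.columns)
        assert (m1["label"] == m2["label"]).all()

    def test_stage_proxy_distribution_matches_config(self):
        # effective diameter should track the drawn uniform diameter closely
        cfg = PhantomConfig(canvas=(96, 96), spacing=(1.0, 1.0),
                            pancreas_radius_frac=(0.2, 0.26),
                            tumor_diameter_range=(6.0, 16.0), noise_sd=0.0)
        cohort, manifest = generate_cohort(cfg, {"cancer": 400}, seed=3)
        sizes = manifest["stage_proxy_mm"].to_numpy()
        stat = kstest(sizes, "uniform", args=(6.0, 10.0))
        assert stat.pvalue > 0.01

    def test_split_is_disjoint_and_stratified(self, tiny_cohort):
        cohort, _ = tiny_cohort
        train, val = train_val_split(cohort, val_fraction=0.25, seed=0)
        assert len(train) + len(val) == len(cohort)
        assert {ls.label for ls in val} == {"normal", "cancer"}


class TestSeparabilityDial:
    def test_larger_tumor_contrast_is_easier(self):
        """A one-feature (mean pancreas HU) threshold classifier should get
        monotonically more accurate as |delta| grows."""
        accs = []
        for delta in (-10.0, -30.0, -70.0):
            cfg = PhantomConfig(canvas=(64, 64), spacing=(2.0, 2.0),
                                pancreas_radius_frac=(0.2, 0.26),
                                tumor_diameter_range=(4.0, 12.0),
                                tumor_delta_range=(delta, delta), noise_sd=15.0)
            cohort, _ = generate_cohort(cfg, 100, seed=17)
            feats = np.array([ls.slice.pixels[ls.slice.region_mask].mean() for ls in cohort])
            labels = np.array([ls.label == "cancer" for ls in cohort])
            thresh = (feats[labels].mean() + feats[~labels].mean()) / 2
            accs.append(((feats < thresh) == labels).mean())
        assert accs[0] <= accs[1] <= accs[2]
        assert accs[2] >= accs[0] + 0.05
        assert accs[2] > 0.75
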