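"""Synthetic abdominal-slice phantoms.

These phantoms stand in for contrast-enhanced pancreas-bearing CT slices:
an elliptical soft-tissue body with a subcutaneous fat ring on an air
background, a brighter pancreas-like parenchymal blob (simulating portal
venous enhancement), and — for the cancer class — a hypodense, ill-margined
tumor blob inside the pancreas.  Correlated Gaussian noise is added last.

They provide the downstream classification task and every test fixture
without any external data.  No claim of anatomical realism is made; the
geometry is deliberately minimal (tumor ⊆ pancreas ⊆ body) and every HU
level is a configuration knob.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.morphology import erosion, disk

import pandas as pd

from .errors import ConfigurationError, GenerationError
from .insertion import ImageSlice


@dataclass
class PhantomConfig:
    """Geometry, tissue HU levels, tumor model and noise model of a phantom.

    Lengths are pixels except ``spacing`` (mm/pixel).  ``stage_proxy`` of a
    generated cancer slice is the tumor's effective diameter in mm, mirroring
    T-stage size stratification (T1-like <= 20 mm, T2-like 20–40 mm).
    """

    canvas: tuple[int, int] = (128, 128)
    spacing: tuple[float, float] = (1.0, 1.0)
    hu_air: float = -1000.0
    hu_body: float = 50.0
    hu_fat: float = -90.0
    hu_pancreas: float = 110.0
    hu_cyst: float = 5.0
    pancreas_radius_frac: tuple[float, float] = (0.18, 0.24)
    tumor_diameter_range: tuple[float, float] = (8.0, 24.0)
    tumor_delta_range: tuple[float, float] = (-60.0, -20.0)
    tumor_feather_sigma: float = 1.0
    noise_sd: float = 15.0
    noise_corr_scale: float = 1.0
    class_scheme: tuple[str, ...] = ("normal", "cancer")

    def __post_init__(self) -> None:
        if self.canvas[0] <= 0 or self.canvas[1] <= 0:
            raise ConfigurationError("canvas must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.tumor_diameter_range
        if not (0 < lo <= hi):
            raise ConfigurationError("tumor_diameter_range must be positive and ordered")
        if self.tumor_delta_range[0] > self.tumor_delta_range[1]:
            raise ConfigurationError("tumor_delta_range min > max")
        for c in self.class_scheme:
            if c not in ("normal", "benign", "cancer"):
                raise ConfigurationError(f"unknown class {c!r}")


@dataclass
class LabeledSlice:
    """A phantom slice with its class label and tumor ground truth."""

    slice: ImageSlice
    label: str
    tumor_mask: np.ndarray
    stage_proxy: float  # tumor effective diameter in mm; NaN for non-cancer

    def __post_init__(self) -> None:
        self.tumor_mask = np.asarray(self.tumor_mask, dtype=bool)
        if (self.label == "cancer") != bool(self.tumor_mask.any()):
            raise ConfigurationError("label is 'cancer' iff tumor_mask is nonempty")


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + ((cc - center[1]) / semi_axes[1]) ** 2 <= 1.0


def _star_blob(shape, center, mean_radius, rng, irregularity=0.15, n_harmonics=3) -> np.ndarray:
    """Star-convex blob: radius modulated by low-order random harmonics."""
    amps = irregularity * rng.uniform(0.3, 1.0, size=n_harmonics) / np.arange(1, n_harmonics + 1)
    phases = rng.uniform(0, 2 * math.pi, size=n_harmonics)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    theta = np.arctan2(dr, dc)
    radius = mean_radius * (
        1.0
        + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
    )
    return dr * dr + dc * dc <= radius * radius


def _tumor_blob(rng, target_diameter: float, irregularity: float = 0.2) -> np.ndarray:
    """Tight-cropped star blob whose effective diameter matches ``target_diameter``.

    Two rasterization passes: the second rescales the mean radius by the
    measured-vs-target area ratio, leaving only sub-pixel quantization error.
    """
    r0 = target_diameter / 2.0
    amps = irregularity * rng.uniform(0.3, 1.0, size=3) / np.arange(1, 4)
    phases = rng.uniform(0, 2 * math.pi, size=3)
    for _pass in range(2):
        side = int(math.ceil(2 * r0 * (1 + irregularity))) + 5
        c = side / 2.0
        rr, cc = np.mgrid[0:side, 0:side]
        dr, dc = rr - c, cc - c
        theta = np.arctan2(dr, dc)
        radius = r0 * (
            1.0 + sum(a * np.cos((k + 1) * theta + p) for k, (a, p) in enumerate(zip(amps, phases)))
        )
        mask = dr * dr + dc * dc <= radius * radius
        area = mask.sum()
        if area == 0:
            raise GenerationError(f"degenerate tumor blob at diameter {target_diameter}")
        eff_d = 2.0 * math.sqrt(area / math.pi)
        r0 *= target_diameter / eff_d
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _containment_centers(region: np.ndarray, blob: np.ndarray) -> np.ndarray:
    """Centers at which ``blob`` placed fully inside ``region``; (k, 2) rows."""
    h, w = blob.shape
    H, W = region.shape
    if h > H or w > W:
        return np.empty((0, 2), dtype=int)
    windows = sliding_window_view(region.astype(np.int64), (h, w))
    counts = np.tensordot(windows, blob.astype(np.int64), axes=([2, 3], [0, 1]))
    tops = np.argwhere(counts == blob.sum())
    return tops + np.array([h // 2, w // 2])


def generate_phantom(
    rng: np.random.Generator, config: PhantomConfig, label: str
) -> LabeledSlice:
    """Generate one labeled phantom slice.

    With ``noise_sd = 0`` and no tumor the image is piecewise constant at the
    configured HU levels.  The tumor is applied as a feathered hypodense
    offset whose drawn diameter is preserved exactly (placement retries keep
    the diameter fixed so the configured size distribution is not biased).
    """
    if label not in config.class_scheme:
        raise ConfigurationError(f"label {label!r} not in class_scheme {config.class_scheme}")
    H, W = config.canvas
    mn = min(H, W)
    body_ax = (0.40 * H * rng.uniform(0.95, 1.05), 0.46 * W * rng.uniform(0.95, 1.05))
    center = (H / 2.0 + rng.uniform(-0.02, 0.02) * H, W / 2.0 + rng.uniform(-0.02, 0.02) * W)
    body = _ellipse_mask((H, W), center, body_ax)
    t = max(2, round(0.04 * mn))
    inner = erosion(body, disk(t))
    ring = body & ~inner

    pixels = np.full((H, W), config.hu_air, dtype=np.float64)
    pixels[body] = config.hu_body
    pixels[ring] = config.hu_fat

    # pancreas: star blob clipped to the inner body region
    safe = erosion(inner, disk(2))
    for _attempt in range(20):
        pc = (
            center[0] + rng.uniform(-0.08, 0.08) * H,
            center[1] + rng.uniform(-0.08, 0.08) * W,
        )
        pr = rng.uniform(*config.pancreas_radius_frac) * mn
        pancreas = _star_blob((H, W), pc, pr, rng) & safe
        if pancreas.sum() >= math.pi * (config.tumor_diameter_range[1] / 2.0) ** 2 * 1.3:
            break
    else:
        raise GenerationError("could not fit a pancreas region inside the body")
    pixels[pancreas] = config.hu_pancreas

    tumor_mask = np.zeros((H, W), dtype=bool)
    stage_proxy = float("nan")
    if label == "cancer":
        d = float(rng.uniform(*config.tumor_diameter_range))
        for _attempt in range(30):
            blob = _tumor_blob(rng, d)
            centers = _containment_centers(pancreas, blob)
            if len(centers) > 0:
                r, c = centers[int(rng.integers(len(centers)))]
                h, w = blob.shape
                tumor_mask[r - h // 2 : r - h // 2 + h, c - w // 2 : c - w // 2 + w] = blob
                break
        else:
            raise GenerationError(
                f"tumor of diameter {d:.1f}px does not fit inside the pancreas "
                f"(diameter range {config.tumor_diameter_range} infeasible)"
            )
        delta = float(rng.uniform(*config.tumor_delta_range))
        if config.tumor_feather_sigma > 0:
            alpha = ndimage.gaussian_filter(
                tumor_mask.astype(np.float64), config.tumor_feather_sigma, mode="constant"
            )
            band = alpha > 0
            pixels[band] += delta * alpha[band]
        else:
            pixels[tumor_mask] += delta
        stage_proxy = 2.0 * math.sqrt(tumor_mask.sum() / math.pi) * config.spacing[0]
    elif label == "benign":
        # cyst-like: sharply bounded, very hypodense (fluid-attenuation), circular
        d = float(rng.uniform(*config.tumor_diameter_range))
        rr = d / 2.0
        blob = _ellipse_mask((int(d) + 3, int(d) + 3), ((int(d) + 2) / 2, (int(d) + 2) / 2), (rr, rr))
        rows = np.flatnonzero(blob.any(axis=1))
        cols = np.flatnonzero(blob.any(axis=0))
        blob = blob[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        centers = _containment_centers(pancreas, blob)
        if len(centers) == 0:
            raise GenerationError(f"cyst of diameter {d:.1f}px does not fit inside the pancreas")
        r, c = centers[int(rng.integers(len(centers)))]
        h, w = blob.shape
        cyst = np.zeros((H, W), dtype=bool)
        cyst[r - h // 2 : r - h // 2 + h, c - w // 2 : c - w // 2 + w] = blob
        pixels[cyst] = config.hu_cyst

    if config.noise_sd > 0:
        noise = rng.standard_normal((H, W))
        if config.noise_corr_scale > 0:
            noise = ndimage.gaussian_filter(noise, config.noise_corr_scale)
        noise *= config.noise_sd / noise.std()  # restore the target sd after blurring
        pixels = pixels + noise

    slc = ImageSlice(pixels, config.spacing, region_mask=pancreas)
    return LabeledSlice(slice=slc, label=label, tumor_mask=tumor_mask, stage_proxy=stage_proxy)


def generate_cohort(
    config: PhantomConfig, n_per_class: dict[str, int] | int, seed: int = 0
) -> tuple[list[LabeledSlice], pd.DataFrame]:
    """Generate a labeled cohort plus its manifest.

    ``n_per_class`` is either a per-class count mapping or a single count
    applied to every class in the scheme.  The manifest records index, label,
    stage proxy (mm) and the master seed; slices are ordered class-by-class
    in scheme order, deterministically.
    """
    if isinstance(n_per_class, int):
        n_per_class = {c: n_per_class for c in config.class_scheme}
    for c, n in n_per_class.items():
        if c not in config.class_scheme:
            raise ConfigurationError(f"class {c!r} not in scheme {config.class_scheme}")
        if n <= 0:
            raise ConfigurationError(f"count for class {c!r} must be positive")
    total = sum(n_per_class.values())
    streams = np.random.SeedSequence(seed).spawn(total)
    out: list[LabeledSlice] = []
    rows = []
    i = 0
    for c in config.class_scheme:
        for _ in range(n_per_class.get(c, 0)):
            ls = generate_phantom(np.random.default_rng(streams[i]), config, c)
            out.append(ls)
            rows.append({"index": i, "label": c, "stage_proxy_mm": ls.stage_proxy, "seed": seed})
            i += 1
    return out, pd.DataFrame(rows)


def train_val_split(
    cohort: list[LabeledSlice], val_fraction: float = 0.25, seed: int = 0
) -> tuple[list[LabeledSlice], list[LabeledSlice]]:
    """Disjoint stratified train/validation split by seeded shuffle."""
    if not (0 < val_fraction < 1):
        raise ConfigurationError("val_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, ls in enumerate(cohort):
        by_class.setdefault(ls.label, []).append(i)
    val_idx: set[int] = set()
    for c in sorted(by_class):
        idx = np.array(by_class[c])
        perm = rng.permutation(len(idx))
        n_val = max(1, int(round(val_fraction * len(idx))))
        val_idx.update(idx[perm[:n_val]].tolist())
    train = [cohort[i] for i in range(len(cohort)) if i not in val_idx]
    val = [cohort[i] for i in range(len(cohort)) if i in val_idx]
    return train, val
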