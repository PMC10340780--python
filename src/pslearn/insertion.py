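"""Lesion insertion: turning clean slices into self-labeled segmentation examples.

The pretext task's supervision is generated here.  A composed pseudo-lesion
is placed inside a slice (inside the organ region when one is available),
its intensity is lowered by a random hypodense offset, and the boundary is
feathered by alpha-compositing with a Gaussian-blurred copy of the mask so
the inserted blob has the ill-defined margin typical of poorly enhancing
tumors.  The emitted ground truth is the *hard* binary mask — the
annotation is pixel-perfect by construction.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import ConfigurationError, GenerationError, PlacementError
from .shapes import LesionConfig, PseudoLesion, compose_pseudo_lesion

PLACEMENTS = ("region-constrained", "anywhere-in-body")


@dataclass
class ImageSlice:
    """A 2D intensity raster in HU-like units.

    ``spacing`` is the (row, col) pixel size in mm.  ``region_mask``, when
    present, marks the organ region admissible for lesion insertion and must
    share the pixel grid of ``pixels`` (row-major, origin top-left).
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    region_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ConfigurationError(f"pixels must be 2D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ConfigurationError("pixels must be finite")
        if not (self.spacing[0] > 0 and self.spacing[1] > 0):
            raise ConfigurationError(f"spacing must be strictly positive, got {self.spacing}")
        if self.region_mask is not None:
            self.region_mask = np.asarray(self.region_mask, dtype=bool)
            if self.region_mask.shape != self.pixels.shape:
                raise ConfigurationError(
                    f"region_mask shape {self.region_mask.shape} != pixels shape {self.pixels.shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy(self) -> "ImageSlice":
        return ImageSlice(
            self.pixels.copy(),
            self.spacing,
            None if self.region_mask is None else self.region_mask.copy(),
        )


@dataclass
class InsertionModel:
    """How a lesion modifies the image.

    ``delta_range`` is the interval the HU offset is drawn from (negative =
    hypodense).  ``feather_sigma`` is the Gaussian scale (pixels) of the
    boundary transition; 0 gives a hard-edged insert.  ``placement`` selects
    whether centers are constrained to the slice's organ region or drawn
    anywhere inside an automatic body mask.
    """

    delta_range: tuple[float, float] = (-60.0, -20.0)
    feather_sigma: float = 1.5
    placement: str = "region-constrained"
    min_inside_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.feather_sigma < 0:
            raise ConfigurationError("feather_sigma must be >= 0")
        if self.placement not in PLACEMENTS:
            raise ConfigurationError(f"placement must be one of {PLACEMENTS}")
        if not (0 < self.min_inside_fraction <= 1):
            raise ConfigurationError("min_inside_fraction must be in (0, 1]")
        if self.delta_range[0] > self.delta_range[1]:
            raise ConfigurationError("delta_range min > max")


@dataclass
class PSExample:
    """One pretext example: image after insertion + the exact binary mask."""

    image: ImageSlice
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


def body_mask(slc: ImageSlice, threshold: float = -500.0) -> np.ndarray:
    """Automatic body mask: threshold, largest 8-connected component, fill holes."""
    m = slc.pixels > threshold
    if not m.any():
        return m
    lab, n = ndimage.label(m, structure=np.ones((3, 3), bool))
    sizes = ndimage.sum_labels(m, lab, index=np.arange(1, n + 1))
    largest = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(largest)


def _overlap_counts(allowed: np.ndarray, lesion_mask: np.ndarray) -> np.ndarray:
    """#lesion pixels falling inside ``allowed`` for every top-left offset."""
    h, w = lesion_mask.shape
    windows = sliding_window_view(allowed.astype(np.int64), (h, w))
    return np.tensordot(windows, lesion_mask.astype(np.int64), axes=([2, 3], [0, 1]))


def admissible_centers(
    slc: ImageSlice, lesion: PseudoLesion, model: InsertionModel
) -> np.ndarray:
    """Exhaustively enumerate all admissible lesion centers, as (k, 2) rows.

    The "center" of a lesion whose mask has shape (h, w) is the pixel at
    local offset (h//2, w//2).  Under region-constrained placement a center
    is admissible when at least ``min_inside_fraction`` of lesion pixels fall
    inside ``region_mask``; under anywhere-in-body, when the center pixel is
    inside the automatic body mask.  The lesion must always lie fully inside
    the slice.
    """
    H, W = slc.shape
    h, w = lesion.mask.shape
    if h > H or w > W:
        raise PlacementError(f"lesion ({h}x{w}) larger than slice ({H}x{W})")
    if model.placement == "region-constrained":
        if slc.region_mask is None:
            raise PlacementError("region-constrained placement requires a region_mask")
        counts = _overlap_counts(slc.region_mask, lesion.mask)
        need = int(math.ceil(model.min_inside_fraction * lesion.area))
        tops = np.argwhere(counts >= need)
    else:
        bm = body_mask(slc)
        centers_grid = bm[h // 2 : h // 2 + (H - h + 1), w // 2 : w // 2 + (W - w + 1)]
        tops = np.argwhere(centers_grid)
    if len(tops) == 0:
        raise PlacementError(
            f"no admissible center for lesion ({h}x{w}) under {model.placement} placement"
        )
    return tops + np.array([h // 2, w // 2])


def choose_placement(
    slc: ImageSlice,
    lesion: PseudoLesion,
    model: InsertionModel,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Draw a placement center uniformly from the admissible set."""
    centers = admissible_centers(slc, lesion, model)
    r, c = centers[int(rng.integers(len(centers)))]
    return int(r), int(c)


def _place_mask(shape: tuple[int, int], lesion: PseudoLesion, center: tuple[int, int]) -> np.ndarray:
    H, W = shape
    h, w = lesion.mask.shape
    top, left = center[0] - h // 2, center[1] - w // 2
    if top < 0 or left < 0 or top + h > H or left + w > W:
        raise PlacementError(f"lesion at center {center} does not fit inside slice {shape}")
    out = np.zeros(shape, dtype=bool)
    out[top : top + h, left : left + w] = lesion.mask
    return out


def recipe_hash(lesion: PseudoLesion) -> str:
    """Stable short hash of a lesion's mask (provenance bookkeeping)."""
    return hashlib.sha256(np.packbits(lesion.mask).tobytes()).hexdigest()[:16]


def insert_lesion(
    slc: ImageSlice,
    lesion: PseudoLesion,
    center: tuple[int, int],
    model: InsertionModel,
    rng: np.random.Generator,
) -> PSExample:
    """Alpha-composite a hypodense lesion into a slice.

    The feather field ``alpha`` is the Gaussian blur (zero-padded, scale
    ``feather_sigma``) of the placed binary mask: 1 deep inside the lesion,
    0 beyond the transition band.  The output pixel is ``input + alpha*delta``
    with ``delta`` drawn uniformly from ``delta_range``; pixels where alpha
    is exactly zero are left bit-identical to the source.  The emitted mask
    is the unblurred binary lesion.
    """
    full_mask = _place_mask(slc.shape, lesion, center)
    delta = float(rng.uniform(*model.delta_range))
    out = slc.pixels.copy()
    if model.feather_sigma > 0:
        alpha = ndimage.gaussian_filter(
            full_mask.astype(np.float64), model.feather_sigma, mode="constant", cval=0.0
        )
        band = alpha > 0
        out[band] += delta * alpha[band]
    else:
        out[full_mask] += delta
    image = ImageSlice(out, slc.spacing, slc.region_mask)
    prov = {
        "center": (int(center[0]), int(center[1])),
        "delta": delta,
        "recipe_hash": recipe_hash(lesion),
        "n_primitives": len(lesion.recipe),
        "effective_diameter": lesion.effective_diameter,
    }
    return PSExample(image=image, mask=full_mask, provenance=prov)


def build_ps_dataset(
    slices: Sequence[ImageSlice],
    lesion_config: LesionConfig,
    insertion_model: InsertionModel,
    n_per_slice: int = 1,
    negative_fraction: float = 0.25,
    seed: int = 0,
) -> list[PSExample]:
    """Generate a fully self-labeled pretext dataset.

    ``round(negative_fraction * total)`` examples (round half up) carry no
    insertion — empty mask, unmodified image — so the segmenter also learns
    to predict absence.  Everything is derived from ``seed``; the same seed
    yields a byte-identical dataset in a deterministic order.
    """
    if not slices:
        raise ConfigurationError("slices must be nonempty")
    if not (0 <= negative_fraction < 1):
        raise ConfigurationError("negative_fraction must be in [0, 1)")
    total = len(slices) * n_per_slice
    n_neg = int(math.floor(negative_fraction * total + 0.5))
    master = np.random.default_rng(seed)
    neg_idx = set(master.choice(total, size=n_neg, replace=False).tolist()) if n_neg else set()
    streams = np.random.SeedSequence(seed).spawn(total)
    out: list[PSExample] = []
    for i in range(total):
        slc = slices[i // n_per_slice]
        if i in neg_idx:
            out.append(
                PSExample(
                    image=slc.copy(),
                    mask=np.zeros(slc.shape, dtype=bool),
                    provenance={"negative": True, "slice_index": i // n_per_slice},
                )
            )
            continue
        rng = np.random.default_rng(streams[i])
        try:
            # a drawn lesion may admit no placement in this particular slice
            # (e.g. too large for its organ region); redraw a bounded number
            # of times before giving up
            for retry in range(10):
                lesion = compose_pseudo_lesion(rng, lesion_config)
                try:
                    center = choose_placement(slc, lesion, insertion_model, rng)
                except PlacementError:
                    if retry == 9:
                        raise
                    continue
                break
            ex = insert_lesion(slc, lesion, center, insertion_model, rng)
        except (PlacementError, GenerationError) as err:
            raise type(err)(f"slice {i // n_per_slice}, example {i}: {err}") from err
        ex.provenance["negative"] = False
        ex.provenance["slice_index"] = i // n_per_slice
        ex.provenance["seed"] = int(streams[i].entropy) if streams[i].entropy is not None else seed
        out.append(ex)
    return out
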