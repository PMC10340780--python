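"""Procedural pseudo-lesion masks.

A pseudo-lesion is a binary mask built as the union of a handful of simple
geometric primitives (circles, rotated ellipses, convex polygons) whose
centers are forced to overlap, yielding a single connected, atypically
shaped blob that mimics the irregular contour of a real tumor.  The union
is optionally smoothed with a morphological closing so that junctions
between primitives do not leave pixel-scale notches.

All randomness flows through a caller-supplied :class:`numpy.random.Generator`,
so the same seed and configuration reproduce bit-identical masks.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.morphology import closing, dilation, disk

from .errors import ConfigurationError, GenerationError

PRIMITIVE_KINDS = ("circle", "ellipse", "convex-polygon")

#: 8-connectivity structuring element used for all connectivity checks.
STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Primitive:
    """A single analytic shape.

    ``center`` is ``(row, col)`` in pixel coordinates; ``size`` holds the
    per-kind parameters:

    - circle: ``{"radius": r}``
    - ellipse: ``{"semi_axes": (a, b)}`` with ``rotation`` in radians
    - convex-polygon: ``{"radii": (...), "angles": (...)}`` — vertex i sits at
      ``center + radii[i] * (sin, cos)(angles[i] + rotation)``; the rasterized
      region is the convex hull of the vertices.
    """

    kind: str
    center: tuple[float, float]
    size: dict
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise ConfigurationError(f"unknown primitive kind {self.kind!r}")
        for v in np.atleast_1d(list(self._size_values())):
            if not np.all(np.asarray(v) > 0):
                raise ConfigurationError(
                    f"{self.kind} size parameters must be strictly positive, got {self.size}"
                )

    def _size_values(self):
        if self.kind == "circle":
            yield self.size["radius"]
        elif self.kind == "ellipse":
            yield from self.size["semi_axes"]
        else:
            yield from self.size["radii"]

    @property
    def effective_size(self) -> float:
        """Radius-like scale: radius, geometric-mean semi-axis, or mean vertex radius."""
        if self.kind == "circle":
            return float(self.size["radius"])
        if self.kind == "ellipse":
            a, b = self.size["semi_axes"]
            return float(math.sqrt(a * b))
        return float(np.mean(self.size["radii"]))

    def inradius(self) -> float:
        """Radius of the largest disc around ``center`` contained in the shape."""
        if self.kind == "circle":
            return float(self.size["radius"])
        if self.kind == "ellipse":
            return float(min(self.size["semi_axes"]))
        pts = self._vertices()
        hull = ConvexHull(pts)
        # hull.equations: rows [A, b] with A @ x + b <= 0 inside
        c = np.asarray(self.center)
        d = -(hull.equations[:, :2] @ c + hull.equations[:, 2])
        return float(d.min())

    def _vertices(self) -> np.ndarray:
        radii = np.asarray(self.size["radii"], dtype=float)
        ang = np.asarray(self.size["angles"], dtype=float) + self.rotation
        r0, c0 = self.center
        return np.column_stack([r0 + radii * np.sin(ang), c0 + radii * np.cos(ang)])


def rasterize(primitive: Primitive, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a primitive onto a canvas.

    A pixel is set iff its integer center lies inside (or on the boundary of)
    the primitive's analytic region; the mask is clipped to the canvas.  An
    empty intersection yields an all-False mask, never an error.
    """
    h, w = int(canvas_shape[0]), int(canvas_shape[1])
    if h <= 0 or w <= 0:
        raise ConfigurationError(f"canvas_shape must be positive, got {canvas_shape}")
    rr, cc = np.mgrid[0:h, 0:w]
    r0, c0 = primitive.center
    if primitive.kind == "circle":
        r = primitive.size["radius"]
        return (rr - r0) ** 2 + (cc - c0) ** 2 <= r * r
    if primitive.kind == "ellipse":
        a, b = primitive.size["semi_axes"]
        th = primitive.rotation
        dr, dc = rr - r0, cc - c0
        u = dc * math.cos(th) + dr * math.sin(th)
        v = -dc * math.sin(th) + dr * math.cos(th)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0
    pts = primitive._vertices()
    hull = ConvexHull(pts)
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    inside = np.all(grid @ hull.equations[:, :2].T + hull.equations[:, 2] <= 1e-9, axis=1)
    return inside.reshape(h, w)


def union_mask(primitives: Sequence[Primitive], canvas_shape: tuple[int, int]) -> np.ndarray:
    """Pixel union (logical OR) of independently rasterized primitives."""
    out = np.zeros(canvas_shape, dtype=bool)
    for p in primitives:
        out |= rasterize(p, canvas_shape)
    return out


@dataclass(frozen=True)
class PseudoLesion:
    """A composed pseudo-lesion: binary mask plus the recipe that produced it.

    ``mask`` is tight-cropped to the lesion's bounding box; ``recipe`` centers
    are expressed in the cropped frame, so re-rasterizing the recipe on
    ``mask.shape`` (without smoothing) reproduces the pre-smoothing union.
    """

    mask: np.ndarray
    recipe: tuple[Primitive, ...]
    effective_diameter: float
    rng_state: dict

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def effective_diameter_mm(self, spacing: tuple[float, float]) -> float:
        """Effective diameter in mm for a given (row, col) pixel spacing.

        Uses the geometric-mean spacing, which is exact for isotropic pixels.
        """
        return self.effective_diameter * math.sqrt(spacing[0] * spacing[1])


@dataclass
class LesionConfig:
    """Knobs for pseudo-lesion composition.

    All lengths are in pixels.  ``size_range`` bounds the per-primitive
    radius-like scale; ``[d_min, d_max]`` bounds the composed lesion's
    effective diameter (diameter of the equal-area circle).
    """

    size_range: tuple[float, float] = (4.0, 14.0)
    count_range: tuple[int, int] = (2, 5)
    d_min: float = 8.0
    d_max: float = 48.0
    smoothing_radius: int = 2
    kinds: tuple[str, ...] = PRIMITIVE_KINDS
    kind_probs: tuple[float, ...] | None = None
    polygon_vertex_range: tuple[int, int] = (5, 9)
    max_retries: int = 100

    def __post_init__(self) -> None:
        lo, hi = self.size_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"size_range must satisfy 0 < min <= max, got {self.size_range}")
        if lo < 1.0:
            raise ConfigurationError("size_range minimum must be >= 1 px for reliable rasterization")
        cmin, cmax = self.count_range
        if not (2 <= cmin <= cmax):
            raise ConfigurationError(f"count_range must satisfy 2 <= min <= max, got {self.count_range}")
        if not (0 < self.d_min <= self.d_max):
            raise ConfigurationError(f"need 0 < d_min <= d_max, got [{self.d_min}, {self.d_max}]")
        if not self.kinds:
            raise ConfigurationError("kinds must be nonempty")
        for k in self.kinds:
            if k not in PRIMITIVE_KINDS:
                raise ConfigurationError(f"unknown primitive kind {k!r}")
        if self.kind_probs is not None:
            if len(self.kind_probs) != len(self.kinds):
                raise ConfigurationError("kind_probs length must match kinds")
            if not math.isclose(sum(self.kind_probs), 1.0, abs_tol=1e-9):
                raise ConfigurationError("kind_probs must sum to 1")
        if self.smoothing_radius < 0:
            raise ConfigurationError("smoothing_radius must be >= 0")


def sample_primitive(
    rng: np.random.Generator,
    size_range: tuple[float, float],
    kinds: Sequence[str] = PRIMITIVE_KINDS,
    kind_probs: Sequence[float] | None = None,
    polygon_vertex_range: tuple[int, int] = (5, 9),
    center: tuple[float, float] = (0.0, 0.0),
) -> Primitive:
    """Draw one primitive with its effective size uniform on ``size_range``.

    The draw is fully determined by the generator state: two fresh streams
    with the same seed produce identical primitives.
    """
    lo, hi = size_range
    if not (0 < lo <= hi):
        raise ConfigurationError(f"size_range must satisfy 0 < min <= max, got {size_range}")
    kinds = tuple(kinds)
    if not kinds:
        raise ConfigurationError("kinds must be nonempty")
    for k in kinds:
        if k not in PRIMITIVE_KINDS:
            raise ConfigurationError(f"unknown primitive kind {k!r}")
    probs = None if kind_probs is None else np.asarray(kind_probs, dtype=float)
    kind = kinds[int(rng.choice(len(kinds), p=probs))]
    s = float(rng.uniform(lo, hi))
    if kind == "circle":
        return Primitive("circle", center, {"radius": s})
    if kind == "ellipse":
        aspect = float(rng.uniform(0.45, 1.0))
        a, b = s / math.sqrt(aspect), s * math.sqrt(aspect)
        rot = float(rng.uniform(0.0, math.pi))
        return Primitive("ellipse", center, {"semi_axes": (a, b)}, rotation=rot)
    nv_lo, nv_hi = polygon_vertex_range
    n = int(rng.integers(nv_lo, nv_hi + 1))
    radii = rng.uniform(0.7, 1.3, size=n)
    radii = radii * (s / radii.mean())  # mean vertex radius == s exactly
    base = 2 * math.pi * np.arange(n) / n
    angles = base + rng.uniform(-0.3, 0.3, size=n) * (2 * math.pi / n)
    rot = float(rng.uniform(0.0, 2 * math.pi))
    return Primitive(
        "convex-polygon", center, {"radii": tuple(radii), "angles": tuple(angles)}, rotation=rot
    )


def _single_component(mask: np.ndarray) -> bool:
    n = ndimage.label(mask, structure=STRUCT8)[1]
    return n == 1


def compose_pseudo_lesion(rng: np.random.Generator, config: LesionConfig) -> PseudoLesion:
    """Compose a connected pseudo-lesion from overlapping random primitives.

    The first primitive anchors the canvas center; each subsequent one is
    centered on a pixel drawn from a dilation of the current union (dilation
    radius = half the new primitive's inradius), which forces raster overlap
    and hence a single 8-connected component.  After an optional morphological
    closing, compositions whose effective diameter falls outside
    ``[d_min, d_max]`` are rejected and redrawn, up to ``max_retries`` times.
    """
    rng_state = rng.bit_generator.state
    side = int(math.ceil(2 * (config.d_max + config.size_range[1]))) + 8
    c0 = side // 2
    for _attempt in range(config.max_retries):
        k = int(rng.integers(config.count_range[0], config.count_range[1] + 1))
        first = sample_primitive(
            rng,
            config.size_range,
            config.kinds,
            config.kind_probs,
            config.polygon_vertex_range,
            center=(float(c0), float(c0)),
        )
        union = rasterize(first, (side, side))
        recipe = [first]
        ok = True
        for _ in range(k - 1):
            p = sample_primitive(
                rng, config.size_range, config.kinds, config.kind_probs, config.polygon_vertex_range
            )
            dil_r = max(1, int(p.inradius() // 2))
            cand = np.argwhere(dilation(union, disk(dil_r)))
            placed = False
            for _try in range(10):
                r, c = cand[int(rng.integers(len(cand)))]
                pc = dataclasses.replace(p, center=(float(r), float(c)))
                new_union = union | rasterize(pc, (side, side))
                if _single_component(new_union):
                    union, placed = new_union, True
                    recipe.append(pc)
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        mask = union
        if config.smoothing_radius > 0:
            mask = closing(mask, disk(config.smoothing_radius))
        eff_d = 2.0 * math.sqrt(mask.sum() / math.pi)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        touches = (
            rows[0] == 0 or cols[0] == 0 or rows[-1] == side - 1 or cols[-1] == side - 1
        )
        if not (config.d_min <= eff_d <= config.d_max) or touches or not _single_component(mask):
            continue
        cropped = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        shifted = tuple(
            dataclasses.replace(
                p, center=(p.center[0] - float(rows[0]), p.center[1] - float(cols[0]))
            )
            for p in recipe
        )
        return PseudoLesion(
            mask=cropped, recipe=shifted, effective_diameter=eff_d, rng_state=rng_state
        )
    raise GenerationError(
        f"could not compose a lesion within {config.max_retries} retries under config {config}"
    )
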