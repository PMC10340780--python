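"""Raster and tabular I/O.

Readers return :class:`~pslearn.insertion.ImageSlice` objects with
intensities as stored (DICOM rescale slope/intercept is the only applied
transform) and pixel spacing from the header; formats without spacing
metadata fall back to 1 mm with a logged warning.  Coordinate convention
throughout: row-major pixel indices, 0-based, origin top-left; masks share
the image frame exactly.

Cohorts and pretext datasets persist as uncompressed NIfTI images, PNG
masks (0/255) and a CSV manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .errors import ConfigurationError
from .insertion import ImageSlice, PSExample
from .phantoms import LabeledSlice

log = logging.getLogger("pslearn")

NIFTI_SUFFIXES = (".nii", ".nii.gz")
DICOM_SUFFIXES = (".dcm", ".dicom")
RASTER_SUFFIXES = (".png", ".tif", ".tiff")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_slice(path, slice_index: int | None = None) -> ImageSlice:
    """Read a 2D slice from NIfTI, DICOM or PNG/TIFF.

    3D NIfTI volumes require an explicit ``slice_index`` (last axis).
    """
    path = Path(path)
    sfx = _suffix(path)
    if sfx in NIFTI_SUFFIXES:
        img = nib.load(str(path))
        data = img.get_fdata()
        zooms = img.header.get_zooms()
        if data.ndim == 3:
            if slice_index is None:
                raise ConfigurationError(f"{path} is a volume; pass slice_index")
            data = data[:, :, slice_index]
        elif data.ndim != 2:
            raise ConfigurationError(f"{path}: unsupported dimensionality {data.ndim}")
        spacing = (float(zooms[0]), float(zooms[1]))
        return ImageSlice(np.asarray(data, dtype=np.float64), spacing)
    if sfx in DICOM_SUFFIXES:
        ds = pydicom.dcmread(str(path))
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        if hasattr(ds, "PixelSpacing"):
            spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        else:
            log.warning("%s: no PixelSpacing; defaulting to 1 mm", path)
            spacing = (1.0, 1.0)
        return ImageSlice(arr, spacing)
    if sfx in RASTER_SUFFIXES:
        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
        log.warning("%s: raster format carries no spacing; defaulting to 1 mm", path)
        return ImageSlice(arr.astype(np.float64), (1.0, 1.0))
    raise ConfigurationError(f"unsupported image format: {path}")


def write_slice(path, slc: ImageSlice) -> None:
    """Write a slice as uncompressed 2D NIfTI (spacing in the header)."""
    path = Path(path)
    if _suffix(path) not in NIFTI_SUFFIXES:
        raise ConfigurationError(f"write_slice writes NIfTI; got {path}")
    affine = np.diag([slc.spacing[0], slc.spacing[1], 1.0, 1.0])
    img = nib.Nifti1Image(slc.pixels.astype(np.float64), affine)
    img.header.set_zooms(slc.spacing)
    nib.save(img, str(path))


def write_mask_png(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask_png(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def mask_to_rle(mask: np.ndarray) -> str:
    """Run-length encode a binary mask as one line of text: ``HxW:start,len;…``
    over the flattened row-major array (0-based starts)."""
    m = np.asarray(mask, bool).ravel()
    padded = np.concatenate([[False], m, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    starts, ends = changes[::2], changes[1::2]
    runs = ";".join(f"{s},{e - s}" for s, e in zip(starts, ends))
    return f"{mask.shape[0]}x{mask.shape[1]}:{runs}"


def mask_from_rle(text: str) -> np.ndarray:
    shape_part, _, runs = text.partition(":")
    h, w = (int(v) for v in shape_part.split("x"))
    m = np.zeros(h * w, dtype=bool)
    if runs:
        for run in runs.split(";"):
            s, ln = (int(v) for v in run.split(","))
            m[s : s + ln] = True
    return m.reshape(h, w)


# -- cohort persistence -------------------------------------------------------

def save_cohort(out_dir, cohort: list[LabeledSlice], manifest: pd.DataFrame) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ls in enumerate(cohort):
        stem = f"slice_{i:04d}"
        write_slice(out / f"{stem}.nii", ls.slice)
        if ls.slice.region_mask is not None:
            write_mask_png(out / f"{stem}_region.png", ls.slice.region_mask)
        if ls.tumor_mask.any():
            write_mask_png(out / f"{stem}_tumor.png", ls.tumor_mask)
        rows.append({"image": f"{stem}.nii", "label": ls.label, "stage_proxy_mm": ls.stage_proxy})
    pd.concat([manifest.reset_index(drop=True), pd.DataFrame(rows)], axis=1).to_csv(
        out / "manifest.csv", index=False
    )


def load_cohort(in_dir) -> tuple[list[LabeledSlice], pd.DataFrame]:
    d = Path(in_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    cohort = []
    for _, row in manifest.iterrows():
        slc = read_slice(d / row["image"])
        stem = Path(row["image"]).stem
        region = d / f"{stem}_region.png"
        if region.exists():
            slc.region_mask = read_mask_png(region)
        tumor_path = d / f"{stem}_tumor.png"
        tumor = read_mask_png(tumor_path) if tumor_path.exists() else np.zeros(slc.shape, bool)
        cohort.append(
            LabeledSlice(slc, row["label"], tumor, float(row["stage_proxy_mm"]))
        )
    return cohort, manifest


def save_ps_dataset(out_dir, examples: list[PSExample]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, ex in enumerate(examples):
        stem = f"ps_{i:04d}"
        write_slice(out / f"{stem}.nii", ex.image)
        write_mask_png(out / f"{stem}_mask.png", ex.mask)
        p = ex.provenance
        rows.append(
            {
                "image": f"{stem}.nii",
                "mask": f"{stem}_mask.png",
                "negative": bool(p.get("negative", not ex.mask.any())),
                "delta": p.get("delta"),
                "center_row": (p.get("center") or (None, None))[0],
                "center_col": (p.get("center") or (None, None))[1],
                "recipe_hash": p.get("recipe_hash"),
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)


def load_ps_dataset(in_dir) -> list[PSExample]:
    d = Path(in_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    out = []
    for _, row in manifest.iterrows():
        img = read_slice(d / row["image"])
        mask = read_mask_png(d / row["mask"])
        out.append(PSExample(img, mask, {"negative": bool(row["negative"])}))
    return out
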