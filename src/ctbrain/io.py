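"""CT volume and binary-mask I/O.

Canonical in-memory layout is a ``(n_slices, n_rows, n_cols)`` integer
HU array with slice index 0 at the most inferior position.  Rows
increase toward the image bottom; all indexing is 0-based.

Supported on-disk forms: a single-frame DICOM series (one file per
slice), NIfTI volumes, and — for masks — NIfTI uint8 or a directory of
per-slice PNGs.
"""
from __future__ import annotations

import glob
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from . import _dicom

log = logging.getLogger(__name__)

HU_MIN = -1024
HU_MAX = 4000


@dataclass
class CTVolume:
    """HU-valued CT stack with spacing metadata.

    ``voxels`` has shape ``(n_slices, n_rows, n_cols)``; slice index
    strictly increases with physical superior position.
    """

    voxels: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (0.469, 0.469)
    slice_thickness_mm: float = 4.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer HU array")
        lo = int(self.voxels.min(initial=0))
        hi = int(self.voxels.max(initial=0))
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values out of plausible CT range [{HU_MIN}, {HU_MAX}]: "
                f"found [{lo}, {hi}]"
            )

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_rows(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_cols(self) -> int:
        return self.voxels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def validate_mask(mask: np.ndarray, shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Coerce to bool and (optionally) check the grid shape."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(np.unique(mask), (0, 1)).all():
            raise ValueError("mask contains values other than 0/1")
        mask = mask.astype(bool)
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match grid {shape}")
    return mask


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (all HU thresholds
    in the pipeline are integers, so ties must not round to even)."""
    values = np.asarray(values, dtype=float)
    return (np.sign(values) * np.floor(np.abs(values) + 0.5)).astype(np.int32)


# ---------------------------------------------------------------------------
# DICOM series

def read_dicom_series(directory_path: str | os.PathLike) -> CTVolume:
    """Load a directory of single-frame CT files into a :class:`CTVolume`.

    Slices are sorted by physical z position into inferior→superior
    order regardless of filename order.  Stored values are converted to
    HU via ``raw * slope + intercept`` and rounded to integers.
    """
    directory = Path(directory_path)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in paths:
        try:
            slices.append((p, _dicom.read_ct_slice(p)))
        except _dicom.DicomError:
            log.debug("skipping non-DICOM file %s", p)
    if not slices:
        raise ValueError(f"no readable DICOM slices in {directory}")

    shapes = {s.raw.shape for _, s in slices}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent matrix sizes across slices: {shapes}")
    for p, s in slices:
        if s.rescale_slope is None or s.rescale_intercept is None:
            raise ValueError(f"{p}: missing rescale slope/intercept metadata")

    zs = [s.z for _, s in slices]
    if len(set(zs)) != len(zs):
        raise ValueError("duplicate slice positions in series")
    slices.sort(key=lambda item: item[1].z)

    hu = np.stack(
        [
            round_half_away(s.raw.astype(np.float64) * s.rescale_slope
                            + s.rescale_intercept)
            for _, s in slices
        ]
    )
    first = slices[0][1]
    spacing = first.pixel_spacing or (1.0, 1.0)
    thickness = first.slice_thickness
    if thickness is None:
        dz = np.diff(sorted(zs))
        thickness = float(np.median(dz)) if dz.size else 1.0
    return CTVolume(hu, (float(spacing[0]), float(spacing[1])), float(thickness))


# ---------------------------------------------------------------------------
# NIfTI volumes

def _nifti_superior_first(img: nib.Nifti1Image) -> bool:
    # k axis maps to scanner z through column 2 of the affine
    return float(img.affine[2, 2]) < 0


def read_volume_file(path: str | os.PathLike) -> CTVolume:
    """Load a NIfTI volume as HU; enforces inferior→superior slice order."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or non-positive voxel spacing")
    data = img.get_fdata()  # applies any scl_slope/scl_inter
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if not np.allclose(data, np.round(data)):
        log.warning("%s: non-integer voxel data rounded to nearest HU", path)
    hu = round_half_away(data)
    # on-disk axes are (col, row, slice); internal layout is (slice, row, col)
    hu = hu.transpose(2, 1, 0)
    if _nifti_superior_first(img):
        hu = hu[::-1].copy()
    return CTVolume(hu, (float(zooms[1]), float(zooms[0])), float(zooms[2]))


def _volume_affine(pixel_spacing_mm: tuple[float, float],
                   slice_thickness_mm: float) -> np.ndarray:
    return np.diag([pixel_spacing_mm[1], pixel_spacing_mm[0],
                    slice_thickness_mm, 1.0])


def write_volume(volume: CTVolume, path: str | os.PathLike) -> None:
    """Write a :class:`CTVolume` as int16 NIfTI (inferior→superior on disk)."""
    data = np.asarray(volume.voxels, dtype=np.int16).transpose(2, 1, 0)
    affine = _volume_affine(volume.pixel_spacing_mm, volume.slice_thickness_mm)
    nib.save(nib.Nifti1Image(data, affine), str(path))


# ---------------------------------------------------------------------------
# Masks

def write_mask(mask: np.ndarray, path: str | os.PathLike,
               format: str = "nifti",
               pixel_spacing_mm: tuple[float, float] = (0.469, 0.469),
               slice_thickness_mm: float = 4.0) -> None:
    """Write a 3-D boolean mask as NIfTI uint8 (1/0) or per-slice PNGs.

    PNG output writes ``slice_<index:03d>.png`` files (8-bit, values 0/1)
    into ``path`` treated as a directory.
    """
    mask = validate_mask(mask)
    if mask.ndim == 2:
        mask = mask[None]
    if format == "nifti":
        data = mask.astype(np.uint8).transpose(2, 1, 0)
        affine = _volume_affine(pixel_spacing_mm, slice_thickness_mm)
        nib.save(nib.Nifti1Image(data, affine), str(path))
    elif format == "png":
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(mask):
            iio.imwrite(outdir / f"slice_{i:03d}.png", sl.astype(np.uint8))
    else:
        raise ValueError(f"unknown mask format {format!r}")


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask written by :func:`write_mask` (NIfTI file or PNG dir)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(glob.glob(str(path / "slice_*.png")))
        if not files:
            raise ValueError(f"no slice_*.png files in {path}")
        return np.stack([np.asarray(iio.imread(f)) > 0 for f in files])
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    mask = (data > 0).transpose(2, 1, 0)
    if _nifti_superior_first(img):
        mask = mask[::-1]
    return mask.copy()
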