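"""Automated per-slice extraction of the brain-tissue region from head CT.

The pipeline runs seven steps on each axial slice, inferior→superior:

1. skin segmentation: threshold at −200 HU, subtract the 7-fold eroded
   body mask from the un-eroded one; the rim is the skin;
2. skin elimination: skin pixels are overwritten with −1000 HU;
3. skull segmentation: threshold at >84 HU, then five 3×3 binary
   dilations to close the orbital openings;
4. ventricle candidates: threshold at <22 HU;
5. distance map: per pixel, the summed ray distance to the (dilated)
   skull along the eight compass directions;
6. foramen-magnum detection: a 20-px-diameter circular template slid
   over the pixels whose distance-map value lies in [100, 250]; the
   most inferior slice where some placement covers more than 100 such
   pixels bounds the analysis range from below;
7. extraction: on slices at/above the detected one, pixels with a
   positive distance map that are neither skull, skin, nor ventricle
   candidates form the brain mask.

All pixel-unit parameters are fixed in pixels (reference geometry:
512×512 matrix, 24 cm field of view) and are not rescaled by pixel
spacing.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from .io import CTVolume

log = logging.getLogger(__name__)

_UNMEASURABLE = np.int32(1 << 30)

#: Step offsets (drow, dcol) for the eight compass directions.
DIRECTIONS: dict[str, tuple[int, int]] = {
    "up": (-1, 0),
    "left_up": (-1, -1),
    "left": (0, -1),
    "left_down": (1, -1),
    "down": (1, 0),
    "right_down": (1, 1),
    "right": (0, 1),
    "right_up": (-1, 1),
}

_KERNEL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass
class ExtractionParams:
    """Numeric configuration of the seven-step pipeline.

    Defaults are the operating point the algorithm was designed at;
    change them only with matching changes to the input geometry.
    """

    skin_binarize_hu: int = -200      # body vs air, inclusive (>=)
    skin_erosions: int = 7
    skull_hu: int = 84                # strict >
    skull_dilations: int = 5
    ventricle_hu: int = 22            # strict <
    kernel_size: int = 3              # full square structuring element
    template_diameter_px: float = 20.0
    dmap_band: tuple[int, int] = (100, 250)   # inclusive bounds
    match_min_px: int = 100           # strict >
    eliminated_hu: int = -1000
    dmap_unmeasurable: str = "any"    # "any" | "all": when Dmap is forced to 0

    def __post_init__(self) -> None:
        if self.skin_erosions < 0 or self.skull_dilations < 0:
            raise ValueError("morphology iteration counts must be >= 0")
        lo, hi = self.dmap_band
        if lo > hi:
            raise ValueError("dmap_band lower bound exceeds upper bound")
        if self.template_diameter_px < 1:
            raise ValueError("template diameter must be >= 1 pixel")
        if self.dmap_unmeasurable not in ("any", "all"):
            raise ValueError("dmap_unmeasurable must be 'any' or 'all'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dmap_band"] = list(self.dmap_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExtractionParams":
        d = dict(d)
        if "dmap_band" in d:
            d["dmap_band"] = tuple(d["dmap_band"])
        return cls(**d)


@dataclass
class ExtractionResult:
    """Final brain mask plus every intermediate the pipeline produced."""

    brain_mask: np.ndarray            # (S, R, C) bool
    skin_mask: np.ndarray
    skull_mask: np.ndarray            # dilated skull
    ventricle_mask: np.ndarray
    dmaps: np.ndarray                 # (S, R, C) int32
    foramen_slice_index: int | None
    params: ExtractionParams

    @property
    def n_extracted_pixels(self) -> int:
        return int(self.brain_mask.sum())


# ---------------------------------------------------------------------------
# Elementary operations

def binarize(slice_values: np.ndarray, threshold_hu: float,
             comparison: str) -> np.ndarray:
    """Threshold one slice; ``comparison`` is one of ``>=``, ``>``, ``<``."""
    a = np.asarray(slice_values)
    if comparison == ">=":
        return a >= threshold_hu
    if comparison == ">":
        return a > threshold_hu
    if comparison == "<":
        return a < threshold_hu
    raise ValueError(f"unsupported comparison {comparison!r}")


def morph(mask: np.ndarray, op: str, iterations: int) -> np.ndarray:
    """Iterated binary erosion/dilation with the full 3×3 square.

    Outside-image pixels are background for both operations.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    if op == "erode":
        return ndimage.binary_erosion(
            mask, structure=_KERNEL_3X3, iterations=iterations, border_value=0)
    if op == "dilate":
        return ndimage.binary_dilation(
            mask, structure=_KERNEL_3X3, iterations=iterations, border_value=0)
    raise ValueError(f"unsupported op {op!r}")


def segment_skin(slice_values: np.ndarray,
                 params: ExtractionParams | None = None) -> np.ndarray:
    """Skin = body mask minus its n-fold erosion (the outer rim)."""
    params = params or ExtractionParams()
    body = binarize(slice_values, params.skin_binarize_hu, ">=")
    return body & ~morph(body, "erode", params.skin_erosions)


def eliminate_skin(slice_values: np.ndarray, skin_mask: np.ndarray,
                   params: ExtractionParams | None = None) -> np.ndarray:
    params = params or ExtractionParams()
    skin_mask = np.asarray(skin_mask, dtype=bool)
    if skin_mask.shape != np.shape(slice_values):
        raise ValueError("skin mask shape does not match slice")
    return np.where(skin_mask, params.eliminated_hu, slice_values)


def segment_skull(skin_eliminated_slice: np.ndarray,
                  params: ExtractionParams | None = None) -> np.ndarray:
    """Dilated high-HU mask; dilation closes orbital openings in the ring."""
    params = params or ExtractionParams()
    bone = binarize(skin_eliminated_slice, params.skull_hu, ">")
    return morph(bone, "dilate", params.skull_dilations)


# ---------------------------------------------------------------------------
# 8-direction distance map

def ray_distance(skull_mask: np.ndarray, pixel: tuple[int, int],
                 direction: str) -> int | None:
    """Steps from ``pixel`` along ``direction`` to the first skull pixel.

    The step landing on the skull pixel is counted (adjacent → 1); a
    diagonal step counts 1.  Returns ``None`` if the ray leaves the
    image, and 0 if the query pixel itself is skull.
    """
    skull_mask = np.asarray(skull_mask, dtype=bool)
    dr, dc = DIRECTIONS[direction]
    r, c = pixel
    if skull_mask[r, c]:
        return 0
    nr, nc = skull_mask.shape
    steps = 0
    while True:
        r += dr
        c += dc
        if not (0 <= r < nr and 0 <= c < nc):
            return None
        steps += 1
        if skull_mask[r, c]:
            return steps


def _scan(skull: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Per-pixel step count to the first skull pixel along (dr, dc).

    dr must be ±1; row r reads its already-processed neighbour row
    r + dr, so rows are visited opposite to the ray direction.
    """
    nr, nc = skull.shape
    out = np.empty((nr, nc), dtype=np.int32)
    rows = range(nr) if dr < 0 else range(nr - 1, -1, -1)
    pad = np.full(1, _UNMEASURABLE, dtype=np.int32)
    for r in rows:
        prev_r = r + dr
        if 0 <= prev_r < nr:
            prev = out[prev_r]
            if dc == 0:
                nbr = prev
            elif dc < 0:
                nbr = np.concatenate((pad, prev[:-1]))
            else:
                nbr = np.concatenate((prev[1:], pad))
            stepped = np.minimum(nbr, _UNMEASURABLE - 1) + 1
            stepped[nbr >= _UNMEASURABLE] = _UNMEASURABLE
        else:
            stepped = np.full(nc, _UNMEASURABLE, dtype=np.int32)
        row = np.where(skull[r], 0, stepped)
        out[r] = row
    return out


def _directional_distances(skull: np.ndarray) -> list[np.ndarray]:
    skull = np.asarray(skull, dtype=bool)
    skull_t = skull.T
    return [
        _scan(skull, -1, 0),                 # up
        _scan(skull, -1, -1),                # left-up
        _scan(skull_t, -1, 0).T,             # left
        _scan(skull, 1, -1),                 # left-down
        _scan(skull, 1, 0),                  # down
        _scan(skull, 1, 1),                  # right-down
        _scan(skull_t, 1, 0).T,              # right
        _scan(skull, -1, 1),                 # right-up
    ]


def compute_dmap(skull_mask: np.ndarray,
                 unmeasurable_policy: str = "any") -> np.ndarray:
    """Summed 8-direction skull distance per pixel (int32, ≥ 0).

    Skull pixels map to 0.  With the default ``"any"`` policy the sum is
    forced to 0 whenever at least one of the eight rays exits the image
    without meeting skull (the sum of eight terms is undefined if any
    term is missing); ``"all"`` zeroes only pixels where no ray is
    measurable and sums the measurable ones otherwise.
    """
    skull = np.asarray(skull_mask, dtype=bool)
    if skull.ndim != 2:
        raise ValueError("skull mask must be 2-D")
    dists = _directional_distances(skull)
    measurable = [d < _UNMEASURABLE for d in dists]
    if unmeasurable_policy == "any":
        ok = np.logical_and.reduce(measurable)
        total = np.zeros(skull.shape, dtype=np.int64)
        for d in dists:
            total += d
        dmap = np.where(ok & ~skull, total, 0)
    elif unmeasurable_policy == "all":
        some = np.logical_or.reduce(measurable)
        total = np.zeros(skull.shape, dtype=np.int64)
        for d, m in zip(dists, measurable):
            total += np.where(m, d, 0)
        dmap = np.where(some & ~skull, total, 0)
    else:
        raise ValueError(f"unknown policy {unmeasurable_policy!r}")
    return dmap.astype(np.int32)


# ---------------------------------------------------------------------------
# Foramen-magnum detection

def circular_template(diameter_px: float) -> np.ndarray:
    """Boolean disk: pixels whose centre lies within diameter/2
    (inclusive, Euclidean) of the template centre."""
    radius = diameter_px / 2.0
    half = int(np.floor(radius))
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1]
    return (dy * dy + dx * dx) <= radius * radius + 1e-9


def template_coverage(band_mask: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Band pixels covered by the template at every integer centre.

    Placements are clipped at image borders; out-of-image positions
    contribute nothing (zero padding).  Exact integer arithmetic.
    """
    return ndimage.convolve(
        np.asarray(band_mask, dtype=np.int32),
        np.asarray(template, dtype=np.int32),
        mode="constant", cval=0)


def detect_foramen_magnum(dmap_stack: np.ndarray | list[np.ndarray],
                          params: ExtractionParams | None = None) -> int | None:
    """Most inferior slice where the circular template covers more than
    ``match_min_px`` pixels of the Dmap band; ``None`` if no slice matches."""
    params = params or ExtractionParams()
    dmaps = list(dmap_stack)
    if len(dmaps) == 0:
        raise ValueError("empty dmap stack")
    template = circular_template(params.template_diameter_px)
    lo, hi = params.dmap_band
    for index, dmap in enumerate(dmaps):
        band = (dmap >= lo) & (dmap <= hi)
        # a placement can never cover more band pixels than exist
        if band.sum() <= params.match_min_px:
            continue
        if template_coverage(band, template).max() > params.match_min_px:
            return index
    return None


# ---------------------------------------------------------------------------
# Full pipeline

def extract_brain(volume: CTVolume,
                  params: ExtractionParams | None = None) -> ExtractionResult:
    """Run the seven-step extraction on every slice of ``volume``."""
    params = params or ExtractionParams()
    shape = volume.shape
    skin = np.zeros(shape, dtype=bool)
    skull = np.zeros(shape, dtype=bool)
    ventricle = np.zeros(shape, dtype=bool)
    dmaps = np.zeros(shape, dtype=np.int32)

    for i in range(volume.n_slices):
        sl = volume.voxels[i]
        skin[i] = segment_skin(sl, params)
        cleaned = eliminate_skin(sl, skin[i], params)
        skull[i] = segment_skull(cleaned, params)
        ventricle[i] = binarize(cleaned, params.ventricle_hu, "<")
        dmaps[i] = compute_dmap(skull[i], params.dmap_unmeasurable)
        log.info("slice %d: skin=%d skull=%d ventricle=%d dmap>0=%d",
                 i, int(skin[i].sum()), int(skull[i].sum()),
                 int(ventricle[i].sum()), int((dmaps[i] > 0).sum()))

    foramen = detect_foramen_magnum(dmaps, params)
    brain = np.zeros(shape, dtype=bool)
    if foramen is None:
        log.warning("foramen magnum not detected; brain mask left empty")
    else:
        candidates = (dmaps > 0) & ~skull & ~ventricle & ~skin
        brain[foramen:] = candidates[foramen:]
        log.info("foramen slice %d; %d brain pixels", foramen, int(brain.sum()))

    return ExtractionResult(
        brain_mask=brain, skin_mask=skin, skull_mask=skull,
        ventricle_mask=ventricle, dmaps=dmaps,
        foramen_slice_index=foramen, params=params)
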