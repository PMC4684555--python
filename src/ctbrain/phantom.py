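"""Synthetic whole-brain CT phantom with per-tissue ground truth.

The phantom stacks, inferior→superior: a few neck slices (soft tissue
plus a solid vertebral bone blob, no enclosing skull), a skull-base
slice whose bone plate carries a circular foramen-magnum aperture with
brainstem inside, and cranial slices with a closed skull ring, a
subarachnoid CSF rim, brain parenchyma around 35 HU and paired low-HU
ventricles.  The three most inferior cranial slices carry anterior
orbital openings in the skull ring so the dilation/closing step is
genuinely exercised.

Tissue layers are carved by Euclidean distance from the head surface,
so layer thicknesses are isotropic in pixels.  All randomness flows
from a single seed; identical (spec, seed) pairs give voxel-identical
volumes.
"""
from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
from scipy import ndimage

from .extraction import ExtractionParams
from .io import CTVolume, round_half_away


@dataclass
class PhantomSpec:
    """Geometry and tissue parameters of the synthetic head."""

    n_slices: int = 40
    n_rows: int = 512
    n_cols: int = 512
    pixel_spacing_mm: tuple[float, float] = (0.469, 0.469)
    slice_thickness_mm: float = 4.0

    # head ellipse semi-axes at full scale (rows = anterior-posterior)
    head_radius_row_px: float = 185.0
    head_radius_col_px: float = 150.0
    # layer depths measured from the head surface (Euclidean, px)
    skin_depth_px: float = 4.0
    subcut_depth_px: float = 9.0
    skull_depth_px: float = 15.0
    csf_depth_px: float = 20.0

    foramen_slice: int = 6
    foramen_radius_px: float = 24.0
    brainstem_csf_px: float = 2.0

    orbital_slices: int = 3
    orbital_gap_px: float = 8.0
    orbital_col_offset_px: float = 35.0

    ventricle_radius_row_px: float = 30.0
    ventricle_radius_col_px: float = 16.0
    ventricle_col_offset_px: float = 28.0
    ventricle_z_halfwidth: float = 7.0

    neck_scale: float = 0.6
    vertebra_radius_px: tuple[float, float] = (18.0, 14.0)
    vertebra_row_offset_px: float = 40.0

    # tissue HU
    background_hu: float = -1000.0
    skin_hu: float = 40.0
    subcut_hu: float = 45.0
    skull_hu: float = 1200.0
    csf_hu: float = 10.0
    orbital_hu: float = -60.0
    brain_hu_mean: float = 35.0
    brain_hu_sd: float = 5.0
    brain_hu_clip: tuple[float, float] = (0.0, 80.0)
    ventricle_hu_mean: float = 8.0
    ventricle_hu_sd: float = 4.0
    noise_sd: float = 3.0

    min_scale: float = 0.2

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomResult:
    volume: CTVolume
    truth_brain: np.ndarray
    truth_skull: np.ndarray
    truth_ventricle: np.ndarray
    truth_skin: np.ndarray
    truth_foramen_slice: int
    spec: PhantomSpec
    seed: int


def default_spec() -> PhantomSpec:
    return PhantomSpec()


def small_spec() -> PhantomSpec:
    """128×128 profile for fast tests; NOT the reference geometry."""
    return PhantomSpec(
        n_rows=128, n_cols=128,
        pixel_spacing_mm=(1.875, 1.875),
        head_radius_row_px=46.0, head_radius_col_px=37.0,
        skin_depth_px=1.0, subcut_depth_px=3.0,
        skull_depth_px=5.0, csf_depth_px=6.5,
        foramen_radius_px=7.0, brainstem_csf_px=1.0,
        orbital_gap_px=3.0, orbital_col_offset_px=9.0,
        ventricle_radius_row_px=8.0, ventricle_radius_col_px=4.0,
        ventricle_col_offset_px=7.0,
        vertebra_radius_px=(5.0, 4.0), vertebra_row_offset_px=10.0,
    )


def small_params() -> ExtractionParams:
    """Pipeline parameters rescaled to the small profile's geometry."""
    return ExtractionParams(
        skin_erosions=2, skull_dilations=2,
        template_diameter_px=5.0, dmap_band=(25, 62), match_min_px=6)


def _ellipse(shape: tuple[int, int], center: tuple[float, float],
             semi: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    a, b = max(semi[0], 1e-6), max(semi[1], 1e-6)
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def _slice_scale(spec: PhantomSpec, index: int) -> float:
    """Half-ellipsoid taper toward the vertex; 1.0 at the skull base."""
    span = spec.n_slices - spec.foramen_slice
    u = (index - spec.foramen_slice) / span
    return float(np.sqrt(max(1.0 - u * u, spec.min_scale ** 2)))


def generate_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> PhantomResult:
    """Build one phantom; deterministic in (spec, seed)."""
    spec = spec or PhantomSpec()
    nr, nc = spec.n_rows, spec.n_cols
    r0, c0 = (nr - 1) / 2.0, (nc - 1) / 2.0
    if (spec.head_radius_row_px + 2 > nr / 2
            or spec.head_radius_col_px + 2 > nc / 2):
        raise ValueError("head geometry does not fit the grid")
    if not (0 < spec.foramen_slice < spec.n_slices - 1):
        raise ValueError("foramen slice index out of range")

    shape = (spec.n_slices, nr, nc)
    vol = np.full(shape, spec.background_hu, dtype=np.float32)
    t_skin = np.zeros(shape, dtype=bool)
    t_skull = np.zeros(shape, dtype=bool)
    t_vent = np.zeros(shape, dtype=bool)
    t_brain = np.zeros(shape, dtype=bool)

    vent_zc = spec.foramen_slice + 12
    f = spec.foramen_slice

    for i in range(spec.n_slices):
        if i < f:
            # neck: soft-tissue oval with a skin rim and a solid vertebra
            neck = _ellipse((nr, nc), (r0, c0),
                            (spec.head_radius_row_px * spec.neck_scale,
                             spec.head_radius_col_px * spec.neck_scale))
            d = ndimage.distance_transform_edt(neck)
            skin = neck & (d <= spec.skin_depth_px)
            vert = _ellipse((nr, nc), (r0 + spec.vertebra_row_offset_px, c0),
                            spec.vertebra_radius_px)
            vol[i][neck] = spec.subcut_hu
            vol[i][skin] = spec.skin_hu
            vol[i][vert] = spec.skull_hu
            t_skin[i] = skin
            t_skull[i] = vert & ~skin
            continue

        s = _slice_scale(spec, i)
        head = _ellipse((nr, nc), (r0, c0),
                        (spec.head_radius_row_px * s,
                         spec.head_radius_col_px * s))
        d = ndimage.distance_transform_edt(head)
        skin = head & (d <= spec.skin_depth_px)
        subcut = (d > spec.skin_depth_px) & (d <= spec.subcut_depth_px)

        if i == f:
            # skull base: bone plate with the foramen-magnum aperture
            aperture = _ellipse((nr, nc), (r0, c0),
                                (spec.foramen_radius_px, spec.foramen_radius_px))
            bone = (d > spec.subcut_depth_px) & ~aperture
            rr, cc = np.ogrid[:nr, :nc]
            rho = np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2)
            stem = aperture & (rho <= spec.foramen_radius_px - spec.brainstem_csf_px)
            csf = aperture & (d > spec.subcut_depth_px) & ~stem
            brain = stem
            vent = np.zeros((nr, nc), dtype=bool)
        else:
            bone = (d > spec.subcut_depth_px) & (d <= spec.skull_depth_px)
            csf = (d > spec.skull_depth_px) & (d <= spec.csf_depth_px)
            interior = d > spec.csf_depth_px
            if 1 <= i - f <= spec.orbital_slices:
                half = spec.orbital_gap_px / 2.0
                cols = np.arange(nc)[None, :]
                rows = np.arange(nr)[:, None]
                anterior = rows < r0
                gap = np.zeros((nr, nc), dtype=bool)
                for sign in (-1, 1):
                    cg = c0 + sign * spec.orbital_col_offset_px * s
                    gap |= anterior & (np.abs(cols - cg) <= half) & bone
                bone = bone & ~gap
                vol[i][gap] = spec.orbital_hu
            vent = np.zeros((nr, nc), dtype=bool)
            w2 = 1.0 - ((i - vent_zc) / spec.ventricle_z_halfwidth) ** 2
            if w2 > 0:
                w = np.sqrt(w2)
                for sign in (-1, 1):
                    vent |= _ellipse(
                        (nr, nc),
                        (r0, c0 + sign * spec.ventricle_col_offset_px),
                        (spec.ventricle_radius_row_px * w,
                         spec.ventricle_radius_col_px * w))
                vent &= interior
            brain = interior & ~vent

        vol[i][subcut] = spec.subcut_hu
        vol[i][skin] = spec.skin_hu
        vol[i][csf] = spec.csf_hu
        vol[i][bone] = spec.skull_hu
        t_skin[i] = skin
        t_skull[i] = bone
        t_vent[i] = vent
        t_brain[i] = brain

    rng = np.random.default_rng(seed)
    n_brain = int(t_brain.sum())
    lo, hi = spec.brain_hu_clip
    vol[t_brain] = np.clip(
        rng.normal(spec.brain_hu_mean, spec.brain_hu_sd, n_brain), lo, hi)
    vol[t_vent] = rng.normal(spec.ventricle_hu_mean, spec.ventricle_hu_sd,
                             int(t_vent.sum()))
    vol += rng.normal(0.0, spec.noise_sd, shape).astype(np.float32)

    hu = round_half_away(vol)
    np.clip(hu, -1024, 4000, out=hu)
    volume = CTVolume(hu, spec.pixel_spacing_mm, spec.slice_thickness_mm)
    return PhantomResult(volume, t_brain, t_skull, t_vent, t_skin, f, spec, seed)


def phantom_suite(n: int, base_spec: PhantomSpec | None = None,
                  seed0: int = 1) -> list[PhantomResult]:
    """n phantoms with jittered geometry (head radii ±10 %, ventricle size
    ±20 %) and seeds ``seed0 .. seed0+n−1``.

    Phantom i depends only on (base_spec, seed0 + i), so a longer suite
    is a superset of a shorter one with the same ``seed0``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base_spec = base_spec or PhantomSpec()
    results = []
    for i in range(n):
        seed = seed0 + i
        jrng = np.random.default_rng(seed)
        f_row = jrng.uniform(0.9, 1.1)
        f_col = jrng.uniform(0.9, 1.1)
        f_vent = jrng.uniform(0.8, 1.2)
        spec = replace(
            base_spec,
            head_radius_row_px=base_spec.head_radius_row_px * f_row,
            head_radius_col_px=base_spec.head_radius_col_px * f_col,
            ventricle_radius_row_px=base_spec.ventricle_radius_row_px * f_vent,
            ventricle_radius_col_px=base_spec.ventricle_radius_col_px * f_vent,
        )
        results.append(generate_phantom(spec, seed))
    return results


def iter_phantom_suite(n: int, base_spec: PhantomSpec | None = None,
                       seed0: int = 1):
    """Generator form of :func:`phantom_suite` (memory-friendly at full scale)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for i in range(n):
        yield phantom_suite(1, base_spec, seed0 + i)[0]
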