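"""CT-number histogram of a masked region and its summary features.

The frequency distribution is tabulated over 22–84 HU (one bin per
integer HU, both bounds inclusive) and summarised by its mean; kurtosis
and skewness are computed over the narrower 22–50 HU window to avoid
heavy tails.  Kurtosis is excess (normal → 0) with population
(moment-based) estimators by default.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import CTVolume

WINDOW_FULL = (22, 84)
WINDOW_SHAPE = (22, 50)


@dataclass
class HistogramReport:
    counts: np.ndarray                  # len 63, bin i ↔ HU 22+i
    n_pixels_22_84: int
    mean_ct_hu: float | None
    n_pixels_22_50: int
    kurtosis_22_50: float | None        # excess kurtosis; None if undefined
    skewness_22_50: float | None

    @property
    def bin_edges_hu(self) -> np.ndarray:
        return np.arange(WINDOW_FULL[0], WINDOW_FULL[1] + 1)

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.tolist(),
            "hu_bins": self.bin_edges_hu.tolist(),
            "n_pixels_22_84": self.n_pixels_22_84,
            "mean_ct_hu": self.mean_ct_hu,
            "n_pixels_22_50": self.n_pixels_22_50,
            "kurtosis_22_50": self.kurtosis_22_50,
            "skewness_22_50": self.skewness_22_50,
        }


def compute_histogram(volume: CTVolume | np.ndarray, mask: np.ndarray,
                      bias: bool = True) -> HistogramReport:
    """Histogram report of the masked voxels of ``volume``.

    ``bias=True`` (default) uses population moment estimators; set False
    for the sample-adjusted (Fisher-corrected) variants.

    An empty mask, or fewer than two distinct values in the 22–50 HU
    window, leaves the affected features ``None``.
    """
    voxels = volume.voxels if isinstance(volume, CTVolume) else np.asarray(volume)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != voxels.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {voxels.shape}")

    values = voxels[mask]
    lo, hi = WINDOW_FULL
    in_full = values[(values >= lo) & (values <= hi)]
    counts = np.bincount((in_full - lo).astype(np.int64),
                         minlength=hi - lo + 1)[: hi - lo + 1]
    n_full = int(in_full.size)
    mean = float(in_full.mean()) if n_full else None

    slo, shi = WINDOW_SHAPE
    in_shape = values[(values >= slo) & (values <= shi)]
    n_shape = int(in_shape.size)
    if n_shape >= 2 and np.unique(in_shape).size >= 2:
        kurt = float(stats.kurtosis(in_shape, fisher=True, bias=bias))
        skew = float(stats.skew(in_shape, bias=bias))
    else:
        kurt = skew = None

    return HistogramReport(
        counts=counts, n_pixels_22_84=n_full, mean_ct_hu=mean,
        n_pixels_22_50=n_shape, kurtosis_22_50=kurt, skewness_22_50=skew)
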