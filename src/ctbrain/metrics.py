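"""Agreement metrics between two binary segmentations.

Counts are pooled over the full grid (one number per volume); a
per-slice breakdown is available for diagnostics.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass
class OverlapMetrics:
    similarity_index: float     # 2·|A∩M| / (|A|+|M|), in [0, 1]
    false_positive_pct: float   # 100·|A∖M| / |M|
    false_negative_pct: float   # 100·|M∖A| / |M|
    n_auto: int
    n_manual: int
    n_intersection: int

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_metrics(auto_mask: np.ndarray,
                    manual_mask: np.ndarray) -> OverlapMetrics:
    """Similarity index and false-positive/-negative rates (percent of the
    reference pixel count).

    Raises ``ValueError`` on shape mismatch or an empty reference mask
    (the rate denominators would be zero).
    """
    auto = np.asarray(auto_mask, dtype=bool)
    manual = np.asarray(manual_mask, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError(
            f"mask shapes differ: {auto.shape} vs {manual.shape}")
    n_auto = int(auto.sum())
    n_manual = int(manual.sum())
    if n_manual == 0:
        raise ValueError("reference mask is empty; rates are undefined")
    n_inter = int((auto & manual).sum())

    si = 2.0 * n_inter / (n_auto + n_manual) if (n_auto + n_manual) else 1.0
    fp = 100.0 * (n_auto - n_inter) / n_manual
    fn = 100.0 * (n_manual - n_inter) / n_manual
    return OverlapMetrics(si, fp, fn, n_auto, n_manual, n_inter)


def per_slice_metrics(auto_mask: np.ndarray,
                      manual_mask: np.ndarray) -> list[OverlapMetrics | None]:
    """Per-slice diagnostics; ``None`` where the reference slice is empty."""
    auto = np.asarray(auto_mask, dtype=bool)
    manual = np.asarray(manual_mask, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError("mask shapes differ")
    out: list[OverlapMetrics | None] = []
    for a, m in zip(auto, manual):
        out.append(overlap_metrics(a, m) if m.any() else None)
    return out
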