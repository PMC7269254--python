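"""Hemispheric vein volumetry and asymmetry statistics.

Per hemisphere the absolute cerebral vein volume (ACVV, ml) is the voxel
count of the vein mask times the voxel volume.  The hemisphere with the
larger ACVV is the calculated dominant hemisphere (CDH); the asymmetry
statistics are

    DCVV  = CDH - CNDH              (ml)
    nDCVV = 100 * DCVV / (CDH + CNDH)   (%)

nDCVV is scale invariant, so it compares subjects with very different total
vein loads.  Note that group means of per-subject nDCVV are not the nDCVV of
group-mean volumes; this module always computes nDCVV per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["AsymmetryResult", "acvv", "asymmetry"]


@dataclass(frozen=True)
class AsymmetryResult:
    """Per-subject hemispheric vein-volume asymmetry."""

    acvv_left: float
    acvv_right: float
    cdh_side: str       # "left" | "right" | "tie"
    cdh: float          # ml, dominant hemisphere
    cndh: float         # ml, non-dominant hemisphere
    dcvv: float         # ml
    ndcvv: float        # percent

    def as_dict(self) -> dict:
        return asdict(self)


def acvv(vein_mask: np.ndarray, spacing) -> float:
    """Absolute cerebral vein volume in ml of a binary mask."""
    spacing = np.asarray(spacing, dtype=float)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be strictly positive")
    mask = np.asarray(vein_mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("vein mask must be binary")
    return float(mask.astype(bool).sum()) * float(np.prod(spacing)) / 1000.0


def asymmetry(acvv_left: float, acvv_right: float) -> AsymmetryResult:
    """Dominance and asymmetry statistics from the two hemisphere volumes.

    Equal volumes (including both zero) give side "tie" with DCVV = nDCVV = 0;
    downstream classification treats ties as showing no venous asymmetry.
    """
    if acvv_left < 0 or acvv_right < 0:
        raise ValueError("hemisphere volumes must be non-negative")
    if acvv_left > acvv_right:
        side = "left"
    elif acvv_right > acvv_left:
        side = "right"
    else:
        side = "tie"
    cdh = max(acvv_left, acvv_right)
    cndh = min(acvv_left, acvv_right)
    dcvv = cdh - cndh
    total = cdh + cndh
    ndcvv = 100.0 * dcvv / total if total > 0 else 0.0
    return AsymmetryResult(acvv_left=float(acvv_left), acvv_right=float(acvv_right),
                           cdh_side=side, cdh=float(cdh), cndh=float(cndh),
                           dcvv=float(dcvv), ndcvv=float(ndcvv))
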