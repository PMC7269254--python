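"""End-to-end quantification: volumes in, asymmetry statistics out."""

from __future__ import annotations

import numpy as np

from .segmentation import SegmentationParams, VeinMask, extract_veins
from .volume_io import HemisphereMask, Volume, split_hemispheres
from .volumetry import AsymmetryResult, acvv, asymmetry

__all__ = ["quantify_volumes", "quantify_phantom"]


def quantify_volumes(swi: Volume, minip: Volume, brain_mask: Volume,
                     exclusion: Volume | None = None,
                     params: SegmentationParams | None = None,
                     ) -> tuple[AsymmetryResult, VeinMask, HemisphereMask]:
    """Segment veins and compute per-hemisphere volumes and asymmetry."""
    hemis = split_hemispheres(brain_mask, exclusion)
    veins = extract_veins(swi, minip, hemis, params)
    a_l = acvv(veins.left, swi.spacing)
    a_r = acvv(veins.right, swi.spacing)
    return asymmetry(a_l, a_r), veins, hemis


def quantify_phantom(truth, params: SegmentationParams | None = None) -> AsymmetryResult:
    """Run the standard pipeline on a generated phantom (no deep-grey exclusion:
    the phantom's parenchyma is homogeneous, so the whole hemisphere is valid)."""
    result, _, _ = quantify_volumes(truth.swi, truth.minip, truth.brain_mask,
                                    exclusion=None, params=params)
    return result
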