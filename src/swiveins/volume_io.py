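"""NIfTI volume I/O, canonical orientation, and hemisphere / exclusion masks.

All volumes are carried as :class:`Volume` objects in canonical RAS+ axis
order (left-to-right, posterior-to-anterior, inferior-to-superior).  The
analysis grid is assumed to live in a symmetric template space whose
mid-sagittal plane is world ``x = 0``; hemisphere membership of a voxel is
decided by the sign of the world x-coordinate of its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "HemisphereMask",
    "read_volume",
    "write_volume",
    "split_hemispheres",
    "make_exclusion_mask",
    "symmetric_affine",
    "DEFAULT_EXCLUSION_CENTER",
    "DEFAULT_EXCLUSION_RADII",
]

#: Midline ellipsoid covering thalami + basal ganglia (template mm).
DEFAULT_EXCLUSION_CENTER = (0.0, -18.0, 8.0)
DEFAULT_EXCLUSION_RADII = (32.0, 38.0, 26.0)

#: Voxel centers within this distance (mm) of x = 0 belong to neither hemisphere.
MIDLINE_TOL_MM = 1e-6


@dataclass
class Volume:
    """A 3D scalar image with its grid-to-world affine.

    Attributes
    ----------
    data:
        3D array of intensities (arbitrary units) or 0/1 mask values.
    affine:
        4x4 grid-to-world map; world coordinates are template-space mm.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains NaN/Inf values")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel edge lengths in mm along the three grid axes."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_coords(self, axis: int = 0) -> np.ndarray:
        """World coordinate of every voxel center along ``axis``, full grid."""
        idx = np.indices(self.shape, dtype=float)
        homog = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)])
        world = np.einsum("ij,jklm->iklm", self.affine, homog)
        return world[axis]

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid with different data."""
        return Volume(np.asarray(data), self.affine.copy())

    def mirrored(self) -> "Volume":
        """Mirror across the mid-sagittal plane (flip the x grid axis).

        Only valid on a symmetric grid where flipping voxel index i -> n-1-i
        negates the world x-coordinate of each voxel center.
        """
        return Volume(self.data[::-1].copy(), self.affine.copy())


@dataclass
class HemisphereMask:
    """Left/right hemisphere masks with a deep-grey/midline exclusion region."""

    left: np.ndarray
    right: np.ndarray
    excluded: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        for name in ("left", "right", "excluded"):
            setattr(self, name, np.asarray(getattr(self, name)).astype(bool))
        if np.any(self.left & self.right) or np.any(self.left & self.excluded) \
                or np.any(self.right & self.excluded):
            raise ValueError("hemisphere masks must be pairwise disjoint")

    @property
    def brain(self) -> np.ndarray:
        """Union of both hemispheres and the excluded region."""
        return self.left | self.right | self.excluded

    def mirrored(self) -> "HemisphereMask":
        """Swap hemispheres by flipping every mask across the x grid axis."""
        return HemisphereMask(
            left=self.right[::-1].copy(),
            right=self.left[::-1].copy(),
            excluded=self.excluded[::-1].copy(),
            affine=self.affine.copy(),
        )


def symmetric_affine(shape: tuple[int, int, int],
                     spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> np.ndarray:
    """RAS+ affine that centers the grid on the world origin.

    Voxel centers along x sit at ``(i - (n-1)/2) * dx`` so that for even n no
    voxel lies exactly on the mid-sagittal plane and flipping the x axis
    negates every x-coordinate exactly.
    """
    aff = np.eye(4)
    for k in range(3):
        aff[k, k] = spacing[k]
        aff[k, 3] = -(shape[k] - 1) / 2.0 * spacing[k]
    return aff


def read_volume(path: str | Path) -> Volume:
    """Load a 3D NIfTI file as a canonically oriented :class:`Volume`.

    Header scaling (scl_slope / scl_inter) is applied; the image is reoriented
    to RAS+ so that the first axis always runs left to right.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[..., 0]
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.get_fdata(dtype=np.float64))
    return Volume(data, np.asarray(img.affine, dtype=float))


def write_volume(vol: Volume, path: str | Path) -> Path:
    """Write a :class:`Volume` as NIfTI (float32; masks stay exact)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))
    return path


def _require_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def split_hemispheres(brain_mask: Volume, exclusion: Volume | None = None) -> HemisphereMask:
    """Partition a brain mask into left / right hemispheres plus exclusions.

    Voxel centers with world x < 0 go left, x > 0 right; centers on the
    mid-sagittal plane (|x| <= 1e-6 mm) are excluded from both so no voxel is
    ever counted twice.  Voxels of the exclusion mask (deep grey nuclei) are
    removed from both hemispheres and reported in ``excluded``.
    """
    bm = _require_binary(brain_mask.data, "brain mask")
    x = brain_mask.world_coords(axis=0)
    if x.min() >= 0 or x.max() <= 0:
        raise ValueError("grid x-range does not straddle the mid-sagittal plane")
    if exclusion is not None:
        if exclusion.data.shape != bm.shape:
            raise ValueError("exclusion mask grid does not match brain mask")
        excl_in = _require_binary(exclusion.data, "exclusion mask")
    else:
        excl_in = np.zeros_like(bm)
    midline = np.abs(x) <= MIDLINE_TOL_MM
    excluded = bm & (excl_in | midline)
    left = bm & (x < -MIDLINE_TOL_MM) & ~excluded
    right = bm & (x > MIDLINE_TOL_MM) & ~excluded
    return HemisphereMask(left=left, right=right, excluded=excluded,
                          affine=brain_mask.affine.copy())


def make_exclusion_mask(grid: Volume,
                        center_mm: tuple[float, float, float] = DEFAULT_EXCLUSION_CENTER,
                        radii_mm: tuple[float, float, float] = DEFAULT_EXCLUSION_RADII,
                        ) -> Volume:
    """Binary ellipsoid in template coordinates on the grid of ``grid``.

    The default covers the thalami and basal ganglia, whose low signal on
    susceptibility-weighted images would otherwise contaminate the vein masks.
    """
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("ellipsoid radii must be strictly positive")
    center = np.asarray(center_mm, dtype=float)
    dist2 = np.zeros(grid.shape)
    for k in range(3):
        dist2 += ((grid.world_coords(axis=k) - center[k]) / radii[k]) ** 2
    return grid.like((dist2 <= 1.0).astype(np.uint8))
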