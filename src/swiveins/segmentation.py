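"""Slice-wise vein segmentation chain for susceptibility-weighted images.

Veins are hypointense on SWI and MinIP.  Each axial slice is processed as:

1. contrast-limited adaptive histogram equalization (CLAHE) restricted to the
   brain region's bounding box;
2. Otsu's threshold on the in-brain pixels;
3. inversion + binarization, fused as "vein = pixel strictly below threshold"
   (thresholding the inverted slice at the inverted threshold is the same
   operation, since 1-x > 1-t  <=>  x < t);
4. white top-hat on the binary slice (slice minus its morphological opening),
   which removes every connected region that can contain the structuring
   element — i.e. the large inverted-background blobs — while keeping thin
   tubular vein cross-sections.

The processed SWI stack (I1) and MinIP stack (I2) are intersected with each
hemisphere mask (H) to give the vein mask V = I1 ∩ I2 ∩ H.

The CLAHE here uses exact integer bilinear tile weights (tile centers are
mirror-symmetric in the slice, and the four interpolation terms are summed in
a flip-stable order), so the whole chain is exactly equivariant under
left-right mirroring of the inputs: flipping the volumes swaps the left and
right vein masks bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import HemisphereMask, Volume

__all__ = [
    "SegmentationParams",
    "VeinMask",
    "DegenerateSliceError",
    "enhance_contrast",
    "otsu_threshold",
    "binarize_invert",
    "tophat",
    "extract_veins",
]

logger = logging.getLogger(__name__)


class DegenerateSliceError(ValueError):
    """Raised when a slice has no contrast (constant inside the brain mask)."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the slice-wise chain.

    clahe_tiles:
        Tile grid for adaptive equalization (rows, cols). Default 8x8.
    clahe_clip:
        Normalized clip limit in (0, 1]; the per-bin histogram ceiling is
        this fraction of the tile's pixel mass (1.0 disables clipping).
    otsu_bins:
        Histogram resolution for threshold selection.
    tophat_size:
        Side length of the square structuring element in pixels.
    tophat_grayscale:
        Apply the top-hat to the grayscale inverted slice before
        binarization instead of to the binary slice.  Off by default.
    """

    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01
    clahe_nbins: int = 256
    otsu_bins: int = 256
    tophat_size: int = 3
    tophat_grayscale: bool = False


@dataclass
class VeinMask:
    """Binary 3D vein mask with the intermediates it was derived from."""

    left: np.ndarray
    right: np.ndarray
    i1: np.ndarray  # processed SWI stack
    i2: np.ndarray  # processed MinIP stack
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def combined(self) -> np.ndarray:
        return self.left | self.right


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def _axis_tile_weights(n: int, tiles: int):
    """Integer bilinear weights of each pixel w.r.t. the two nearest tile centers.

    Positions are kept as integers scaled by 2n: pixel center (2r+1)*tiles,
    tile center (2i+1)*n, both in units of 1/(2*n*tiles) of the axis length.
    Returns (i0, i1, w0, w1, den) with w0 + w1 == den == 2n exactly; under
    r -> n-1-r the pairs map to the mirrored tiles with w0 and w1 swapped.
    """
    r = np.arange(n, dtype=np.int64)
    den = 2 * n
    u = (2 * r + 1) * tiles - n  # floor(u/den) = tile index left of pixel
    i0 = u // den
    w1 = u - i0 * den
    w0 = den - w1
    i1 = i0 + 1
    return (np.clip(i0, 0, tiles - 1), np.clip(i1, 0, tiles - 1), w0, w1, den)


def _clahe(img: np.ndarray, tiles: tuple[int, int], clip: float, nbins: int) -> np.ndarray:
    """CLAHE on a [0,1] image with mirror-symmetric tile interpolation."""
    h, w = img.shape
    tr, tc = max(int(tiles[0]), 1), max(int(tiles[1]), 1)
    b = np.minimum((img * nbins).astype(np.int64), nbins - 1)

    ri0, ri1, rw0, rw1, rden = _axis_tile_weights(h, tr)
    ci0, ci1, cw0, cw1, cden = _axis_tile_weights(w, tc)

    # tile histograms: each pixel contributes its bilinear weight to the
    # histograms of its 4 neighbouring tiles (integer weights -> exact sums)
    hist = np.zeros(tr * tc * nbins, dtype=np.int64)
    for ri, rw in ((ri0, rw0), (ri1, rw1)):
        for ci, cw in ((ci0, cw0), (ci1, cw1)):
            key = (ri[:, None] * tc + ci[None, :]) * nbins + b
            wt = rw[:, None] * cw[None, :]
            hist += np.bincount(key.ravel(), weights=wt.ravel(),
                                minlength=tr * tc * nbins).astype(np.int64)
    hist = hist.reshape(tr, tc, nbins)

    tot = hist.sum(axis=-1)
    limit = np.maximum((clip * tot).astype(np.int64), 1)
    clipped = np.minimum(hist, limit[..., None])
    excess = tot - clipped.sum(axis=-1)
    clipped += (excess // nbins)[..., None]
    rem = excess % nbins
    clipped += np.arange(nbins)[None, None, :] < rem[..., None]
    cdf = np.cumsum(clipped, axis=-1)
    mapping = cdf / tot[..., None]  # in (0, 1]

    m00 = mapping[ri0[:, None], ci0[None, :], b]
    m01 = mapping[ri0[:, None], ci1[None, :], b]
    m10 = mapping[ri1[:, None], ci0[None, :], b]
    m11 = mapping[ri1[:, None], ci1[None, :], b]
    w00 = (rw0[:, None] * cw0[None, :]).astype(np.float64)
    w01 = (rw0[:, None] * cw1[None, :]).astype(np.float64)
    w10 = (rw1[:, None] * cw0[None, :]).astype(np.float64)
    w11 = (rw1[:, None] * cw1[None, :]).astype(np.float64)
    # fixed summation tree: flips only permute terms within commutative sums
    s0 = w00 * m00 + w01 * m01
    s1 = w10 * m10 + w11 * m11
    return (s0 + s1) / float(rden * cden)


def enhance_contrast(pixels: np.ndarray, in_slice_mask: np.ndarray,
                     tiles: tuple[int, int] = (8, 8), clip_limit: float = 0.01,
                     nbins: int = 256) -> np.ndarray:
    """Adaptive histogram equalization of a [0,1] slice inside the brain bbox.

    Equalization runs on the bounding box of ``in_slice_mask``; pixels outside
    the bounding box are returned unchanged.  A slice with an empty mask or no
    contrast inside the bounding box passes through unchanged.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if not np.all(np.isfinite(pixels)):
        raise ValueError("slice contains non-finite pixels")
    if not (0 < clip_limit <= 1):
        raise ValueError("clip_limit must be in (0, 1]")
    mask = np.asarray(in_slice_mask, dtype=bool)
    if mask.shape != pixels.shape:
        raise ValueError("mask shape does not match slice shape")
    if not mask.any():
        logger.debug("empty in-slice mask: slice passed through unchanged")
        return pixels.copy()
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sl = (slice(rows[0], rows[-1] + 1), slice(cols[0], cols[-1] + 1))
    crop = pixels[sl]
    out = pixels.copy()
    if crop.max() - crop.min() <= 0:
        return out  # constant region: nothing to equalize
    crop01 = np.clip(crop, 0.0, 1.0)
    out[sl] = _clahe(crop01, tiles, clip_limit, nbins)
    return out


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def otsu_threshold(pixels: np.ndarray, in_slice_mask: np.ndarray | None = None,
                   bins: int = 256) -> float:
    """Otsu's threshold of the in-mask pixels of a slice.

    Exhaustively maximizes the between-class variance over all histogram bin
    boundaries and returns the boundary value (upper edge of the lower
    class).  Raises :class:`DegenerateSliceError` for constant input.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    vals = pixels[np.asarray(in_slice_mask, dtype=bool)] if in_slice_mask is not None \
        else pixels.ravel()
    if vals.size == 0 or vals.min() == vals.max():
        raise DegenerateSliceError("slice is constant inside the mask")
    hist, edges = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(np.float64)
    total = w.sum()
    cw0 = np.cumsum(w)[:-1]          # lower-class mass at cut k = 0..bins-2
    cw1 = total - cw0
    csum = np.cumsum(w * centers)[:-1]
    tsum = float((w * centers).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / cw0
        mu1 = (tsum - csum) / cw1
        sigma_b = cw0 * cw1 * (mu0 - mu1) ** 2
    sigma_b[(cw0 == 0) | (cw1 == 0)] = -np.inf
    k = int(np.argmax(sigma_b))      # first maximum on ties
    return float(edges[k + 1])


def binarize_invert(pixels: np.ndarray, threshold: float,
                    in_slice_mask: np.ndarray | None = None) -> np.ndarray:
    """Dark-vein binarization: 1 where pixel < threshold inside the mask.

    Equivalent to inverting the slice (veins white) and thresholding above
    the inverted cutoff; a pixel exactly at the threshold is background.
    """
    pixels = np.asarray(pixels)
    out = pixels < threshold
    if in_slice_mask is not None:
        out = out & np.asarray(in_slice_mask, dtype=bool)
    return out


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

def tophat(binary_slice: np.ndarray, se: np.ndarray | int = 3) -> np.ndarray:
    """White top-hat of a binary slice: input minus its morphological opening.

    The opening is erosion followed by dilation with the structuring element
    (default 3x3 square); erosion treats pixels beyond the border as
    background, so foreground touching the border erodes.  Structures that
    fully contain the element are removed; thin and small ones are kept.
    """
    img = np.asarray(binary_slice).astype(bool)
    if isinstance(se, (int, np.integer)):
        se = np.ones((int(se), int(se)), dtype=bool)
    se = np.asarray(se).astype(bool)
    if not se.any():
        raise ValueError("structuring element is empty")
    opened = ndimage.binary_opening(img, structure=se, border_value=0)
    return img & ~opened


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def _normalize01(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Scale a volume to [0,1] using the in-brain intensity range."""
    vals = data[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        return np.zeros_like(data, dtype=np.float64)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


def _process_stack(data: np.ndarray, brain: np.ndarray,
                   params: SegmentationParams) -> np.ndarray:
    """Run the slice-wise chain on one volume; returns a binary 3D stack."""
    norm = _normalize01(data, brain)
    out = np.zeros(data.shape, dtype=bool)
    for k in range(data.shape[2]):
        msk = brain[:, :, k]
        if not msk.any():
            continue
        enh = enhance_contrast(norm[:, :, k], msk, tiles=params.clahe_tiles,
                               clip_limit=params.clahe_clip, nbins=params.clahe_nbins)
        try:
            thr = otsu_threshold(enh, msk, bins=params.otsu_bins)
        except DegenerateSliceError:
            logger.debug("slice %d degenerate after enhancement: skipped", k)
            continue
        if params.tophat_grayscale:
            inv = np.where(msk, 1.0 - enh, 0.0)
            se = np.ones((params.tophat_size, params.tophat_size), dtype=bool)
            residual = inv - ndimage.grey_opening(inv, footprint=se, mode="constant", cval=0.0)
            binary = (residual > (1.0 - thr)) & msk
        else:
            binary = binarize_invert(enh, thr, msk)
            binary = tophat(binary, params.tophat_size)
        out[:, :, k] = binary
    return out


def extract_veins(swi: Volume, minip: Volume, hemis: HemisphereMask,
                  params: SegmentationParams | None = None) -> VeinMask:
    """Segment veins and split them by hemisphere: V = I1 ∩ I2 ∩ H.

    The SWI and MinIP volumes are processed independently with the slice-wise
    chain, intersected with each other and with the left / right hemisphere
    masks (deep grey exclusions are already absent from those masks).
    """
    params = params or SegmentationParams()
    if swi.shape != minip.shape or not np.allclose(swi.affine, minip.affine):
        raise ValueError("SWI and MinIP are not on the same grid")
    if swi.shape != hemis.left.shape:
        raise ValueError("hemisphere masks are not on the image grid")
    brain = hemis.left | hemis.right
    if not brain.any():
        raise ValueError("empty brain mask")
    i1 = _process_stack(swi.data, brain, params)
    i2 = _process_stack(minip.data, brain, params)
    veins = i1 & i2
    return VeinMask(left=veins & hemis.left, right=veins & hemis.right,
                    i1=i1, i2=i2, affine=swi.affine.copy())
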