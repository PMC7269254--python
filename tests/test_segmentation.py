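from fractions import Fraction

import numpy as np
import pytest

from swiveins import (DegenerateSliceError, SegmentationParams, binarize_invert,
                      enhance_contrast, extract_veins, otsu_threshold,
                      split_hemispheres, tophat)
from swiveins.segmentation import _normalize01


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def otsu_oracle(vals, bins=256):
    """Exhaustive search of the between-class variance in exact arithmetic."""
    hist, edges = np.histogram(vals, bins=bins, range=(vals.min(), vals.max()))
    centers = [(Fraction(edges[i]) + Fraction(edges[i + 1])) / 2 for i in range(bins)]
    counts = [int(c) for c in hist]
    total = sum(counts)
    tsum = sum(Fraction(c) * m for c, m in zip(counts, centers))
    best_k, best_sigma = None, None
    w0 = Fraction(0)
    csum = Fraction(0)
    for k in range(bins - 1):
        w0 += counts[k]
        csum += counts[k] * centers[k]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = csum / w0
        mu1 = (tsum - csum) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if best_sigma is None or sigma > best_sigma:
            best_sigma, best_k = sigma, k
    return edges[best_k + 1]


def erode_oracle(img, se):
    """Direct erosion with zero padding (border counts as background)."""
    h, w = img.shape
    sh, sw = se.shape
    oy, ox = sh // 2, sw // 2
    out = np.zeros_like(img, dtype=bool)
    for i in range(h):
        for j in range(w):
            ok = True
            for a in range(sh):
                for b in range(sw):
                    if not se[a, b]:
                        continue
                    y, x = i + a - oy, j + b - ox
                    if y < 0 or y >= h or x < 0 or x >= w or not img[y, x]:
                        ok = False
                        break
                if not ok:
                    break
            out[i, j] = ok
    return out


def dilate_oracle(img, se):
    h, w = img.shape
    sh, sw = se.shape
    oy, ox = sh // 2, sw // 2
    out = np.zeros_like(img, dtype=bool)
    for i in range(h):
        for j in range(w):
            hit = False
            for a in range(sh):
                for b in range(sw):
                    if not se[a, b]:
                        continue
                    y, x = i - (a - oy), j - (b - ox)
                    if 0 <= y < h and 0 <= x < w and img[y, x]:
                        hit = True
                        break
                if hit:
                    break
            out[i, j] = hit
    return out


def tophat_oracle(img, se):
    return img & ~dilate_oracle(erode_oracle(img, se), se)


# ---------------------------------------------------------------------------
# enhance_contrast
# ---------------------------------------------------------------------------

class TestEnhanceContrast:
    def test_constant_slice_maps_to_constant(self):
        img = np.full((32, 32), 0.5)
        mask = np.ones_like(img, dtype=bool)
        out = enhance_contrast(img, mask)
        assert np.all(out == out.flat[0])

    def test_output_range_contract(self):
        rng = np.random.default_rng(0)
        img = rng.random((40, 48))
        mask = rng.random((40, 48)) > 0.2
        out = enhance_contrast(img, mask)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_two_level_slice_gets_more_separated(self):
        # equal-area 0.4/0.6 image, single tile, no clipping: the equalized
        # two-bin histogram maps the levels to cdf values 0.5 and 1.0
        img = np.full((16, 16), 0.4)
        img[:, 8:] = 0.6
        mask = np.ones_like(img, dtype=bool)
        out = enhance_contrast(img, mask, tiles=(1, 1), clip_limit=1.0)
        lo = out[img == 0.4].mean()
        hi = out[img == 0.6].mean()
        assert lo == pytest.approx(0.5)
        assert hi == pytest.approx(1.0)
        assert hi - lo > 0.6 - 0.4

    def test_background_outside_bbox_untouched(self):
        rng = np.random.default_rng(1)
        img = rng.random((30, 30))
        mask = np.zeros_like(img, dtype=bool)
        mask[5:15, 8:20] = True
        out = enhance_contrast(img, mask)
        bbox = np.zeros_like(mask)
        bbox[5:15, 8:20] = True
        assert np.array_equal(out[~bbox], img[~bbox])

    def test_empty_mask_passes_through(self):
        img = np.random.default_rng(2).random((10, 10))
        out = enhance_contrast(img, np.zeros_like(img, dtype=bool))
        assert np.array_equal(out, img)

    def test_mirror_equivariance_exact(self):
        rng = np.random.default_rng(3)
        img = rng.random((33, 41))  # odd sizes: the hard case for tiling
        mask = rng.random(img.shape) > 0.15
        out = enhance_contrast(img, mask)
        out_f = enhance_contrast(img[:, ::-1].copy(), mask[:, ::-1].copy())
        assert np.array_equal(out_f, out[:, ::-1])


# ---------------------------------------------------------------------------
# otsu_threshold
# ---------------------------------------------------------------------------

class TestOtsu:
    def test_perfect_bimodality(self):
        vals = np.array([0.0] * 4 + [1.0] * 4)
        t = otsu_threshold(vals.reshape(2, 4))
        assert 0.0 < t < 1.0
        assert (vals < t).sum() == 4

    def test_matches_bruteforce_on_stated_example(self):
        vals = np.array([0, 0, 0, 0.1, 0.1, 0.9, 0.9, 1.0])
        t = otsu_threshold(vals.reshape(2, 4), bins=256)
        assert t == pytest.approx(otsu_oracle(vals, bins=256), abs=1e-12)
        assert (vals < t).sum() == 5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 400)
        vals = np.concatenate([rng.normal(0.3, 0.1, n), rng.normal(0.7, 0.15, n // 2)])
        bins = int(rng.choice([16, 64, 256]))
        t = otsu_threshold(vals.reshape(1, -1), bins=bins)
        assert t == pytest.approx(otsu_oracle(vals, bins=bins), rel=1e-12)

    def test_deterministic(self):
        vals = np.random.default_rng(5).random((8, 8))
        assert otsu_threshold(vals) == otsu_threshold(vals + 0.0)

    def test_in_mask_pixels_only(self):
        img = np.zeros((4, 4))
        img[:2] = 10.0  # huge outliers outside the mask
        img[2:] = np.linspace(0.1, 0.9, 8).reshape(2, 4)
        mask = np.zeros_like(img, dtype=bool)
        mask[2:] = True
        t = otsu_threshold(img, mask)
        assert t < 1.0

    def test_constant_slice_is_degenerate(self):
        with pytest.raises(DegenerateSliceError):
            otsu_threshold(np.full((4, 4), 0.5))


# ---------------------------------------------------------------------------
# binarize_invert
# ---------------------------------------------------------------------------

class TestBinarizeInvert:
    def test_all_above_threshold_gives_empty(self):
        img = np.full((4, 4), 0.9)
        assert not binarize_invert(img, 0.5).any()

    def test_exact_tie_is_background(self):
        img = np.full((2, 2), 0.5)
        assert not binarize_invert(img, 0.5).any()

    def test_checkerboard_example(self):
        img = np.array([[0.2, 0.8], [0.8, 0.2]])
        assert np.array_equal(binarize_invert(img, 0.5),
                              np.array([[1, 0], [0, 1]], dtype=bool))

    def test_inversion_equivalence(self):
        # thresholding the inverted slice above 1-t equals "pixel < t"
        rng = np.random.default_rng(6)
        img = rng.random((16, 16))
        t = 0.37
        assert np.array_equal(binarize_invert(img, t), (1.0 - img) > (1.0 - t))


# ---------------------------------------------------------------------------
# tophat
# ---------------------------------------------------------------------------

class TestTophat:
    def test_empty_input(self):
        assert not tophat(np.zeros((8, 8), dtype=bool)).any()

    def test_isolated_pixel_retained(self):
        img = np.zeros((9, 9), dtype=bool)
        img[4, 4] = True
        out = tophat(img, 3)
        assert np.array_equal(out, tophat_oracle(img, np.ones((3, 3), dtype=bool)))
        assert out[4, 4]

    def test_solid_block_interior_removed(self):
        img = np.zeros((11, 11), dtype=bool)
        img[3:8, 3:8] = True
        out = tophat(img, 3)
        assert np.array_equal(out, tophat_oracle(img, np.ones((3, 3), dtype=bool)))
        assert not out[5, 5]  # interior of a 5x5 block is opened away

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_bruteforce_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.random((15, 17)) > rng.uniform(0.3, 0.7)
        out = tophat(img, 3)
        assert np.array_equal(out, tophat_oracle(img, np.ones((3, 3), dtype=bool)))
        assert np.all(out <= img)  # anti-extensive

    def test_opening_idempotent(self):
        from scipy import ndimage
        rng = np.random.default_rng(9)
        img = rng.random((20, 20)) > 0.4
        se = np.ones((3, 3), dtype=bool)
        once = ndimage.binary_opening(img, structure=se, border_value=0)
        twice = ndimage.binary_opening(once, structure=se, border_value=0)
        assert np.array_equal(once, twice)


# ---------------------------------------------------------------------------
# extract_veins
# ---------------------------------------------------------------------------

class TestExtractVeins:
    def test_staged_oracle_equivalence(self, small_phantom):
        """extract_veins equals the manual slice-wise composition of its stages."""
        ph = small_phantom
        hemis = split_hemispheres(ph.brain_mask)
        params = SegmentationParams()
        veins = extract_veins(ph.swi, ph.minip, hemis, params)

        brain = hemis.left | hemis.right
        stacks = []
        for vol in (ph.swi, ph.minip):
            norm = _normalize01(vol.data, brain)
            stack = np.zeros(vol.shape, dtype=bool)
            for k in range(vol.shape[2]):
                msk = brain[:, :, k]
                if not msk.any():
                    continue
                enh = enhance_contrast(norm[:, :, k], msk,
                                       tiles=params.clahe_tiles,
                                       clip_limit=params.clahe_clip)
                try:
                    thr = otsu_threshold(enh, msk, bins=params.otsu_bins)
                except DegenerateSliceError:
                    continue
                stack[:, :, k] = tophat(binarize_invert(enh, thr, msk),
                                        params.tophat_size)
            stacks.append(stack)
        expect = stacks[0] & stacks[1]
        assert np.array_equal(veins.left, expect & hemis.left)  # Dice = 1
        assert np.array_equal(veins.right, expect & hemis.right)

    def test_containment_in_intermediates_and_hemisphere(self, small_phantom):
        ph = small_phantom
        hemis = split_hemispheres(ph.brain_mask)
        veins = extract_veins(ph.swi, ph.minip, hemis)
        v = veins.combined
        assert np.all(v <= veins.i1) and np.all(v <= veins.i2)
        assert np.all(veins.left <= hemis.left) and np.all(veins.right <= hemis.right)
        assert not np.any(veins.left & veins.right)

    def test_disjoint_stacks_give_empty_veins(self, small_phantom):
        # SWI with veins only dark where MinIP is uniform: intersection empty
        ph = small_phantom
        hemis = split_hemispheres(ph.brain_mask)
        const = ph.swi.like(np.where(ph.brain_mask.data > 0, 1.0, 0.0))
        veins = extract_veins(const, ph.minip, hemis)
        assert not veins.combined.any()  # constant slices contribute nothing

    def test_mirror_equivariance_exact(self, small_phantom):
        ph = small_phantom
        hemis = split_hemispheres(ph.brain_mask)
        veins = extract_veins(ph.swi, ph.minip, hemis)
        veins_m = extract_veins(ph.swi.mirrored(), ph.minip.mirrored(),
                                split_hemispheres(ph.brain_mask.mirrored()))
        assert np.array_equal(veins_m.left, veins.right[::-1])
        assert np.array_equal(veins_m.right, veins.left[::-1])

    def test_deterministic_rerun(self, small_phantom):
        ph = small_phantom
        hemis = split_hemispheres(ph.brain_mask)
        a = extract_veins(ph.swi, ph.minip, hemis)
        b = extract_veins(ph.swi, ph.minip, hemis)
        assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)

    def test_grid_mismatch_rejected(self, small_phantom, symmetric_grid):
        ph = small_phantom
        hemis = split_hemispheres(ph.brain_mask)
        with pytest.raises(ValueError, match="grid"):
            extract_veins(ph.swi, symmetric_grid, hemis)
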