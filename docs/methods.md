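# Methods

## Scope and input contract

The pipeline quantifies cerebral veins on SWI/MinIP volume pairs that are
already co-registered and spatially normalized to a symmetric template grid
whose mid-sagittal plane is world *x* = 0. Nonlinear registration is an
external concern: inputs are assumed pre-normalized, or a 4×4 affine can be
supplied and is applied by `preprocess.resample_to_grid` (linear for
intensities, nearest for masks, out-of-field voxels filled with 0). All
volumes are reoriented to RAS+ at load so "left" is unambiguous; header
scaling is applied; non-finite voxels are rejected rather than silently
repaired.

Hemisphere membership of a voxel is the sign of the world x-coordinate of
its center; centers within 1e-6 mm of the plane belong to neither
hemisphere, which makes the split deterministic and prevents double
counting. The deep grey nuclei (thalami, basal ganglia) have low SWI signal
and would contaminate the vein masks; they are removed by a configurable
midline ellipsoid — default center (0, −18, 8) mm, radii (32, 38, 26) mm in
template coordinates — chosen to generously cover that region on a
template-space adult brain. A user-supplied exclusion mask overrides it. No
atlas is bundled: the ellipsoid is a geometric stand-in the user can replace.

## Minimum intensity projection

When no scanner MinIP exists it is derived from SWI. For each output slice,
every in-plane position carries the minimum over the axial slices whose
centers fall within the slab window. Default slab thickness is 14 mm
(typical of clinical MinIP reconstructions, which range roughly 13–16 mm)
with the slab centered on each SWI slice (sliding window), so the MinIP is
voxelwise comparable to the SWI and the later intersection I₁ ∩ I₂ is well
defined. A block mode (`step_mm == thickness_mm`) reproduces non-overlapping
scanner-style slabs, each block minimum broadcast to its slices. The
projection is anti-extensive (output ≤ input) and monotone in slab
thickness; it is idempotent in block mode, while re-applying the sliding
form widens the effective window (the composition of two width-w minimum
filters is a width-(2w−1) filter), which is why the idempotence test uses
block mode.

## Slice-wise segmentation chain

Intensities are first scaled to [0, 1] using the in-brain range of the whole
volume, then each axial slice runs CLAHE → Otsu → binarize/invert → top-hat.

**CLAHE.** Tile grid 8×8, normalized clip limit 0.01, 256 bins (the
conventional defaults of the adaptive-equalization operation), all
configurable. Equalization is restricted to the bounding box of the in-slice
brain mask — the dark exterior would otherwise dominate every tile histogram
— and pixels outside the box are untouched. The implementation is written
in-package with one numerical property the off-the-shelf routines do not
guarantee: exact mirror equivariance. Tile centers are placed symmetrically
in the slice, each pixel contributes to the histograms of its four
neighbouring tiles with *integer* bilinear weights (numerator/denominator
kept exactly; histogram sums accumulate integers, so they are
order-independent), and the four interpolation terms are summed in a fixed
tree in which a flip only permutes operands of commutative additions.
Flipping a slice therefore flips its output bit for bit, and mirroring the
input volumes swaps the left and right vein masks exactly — a strong
end-to-end invariant that rules out any left/right processing bias.
Clipping redistributes the excess uniformly across bins (remainder to the
lowest bins); a constant region is returned unchanged.

**Otsu.** The threshold maximizes the between-class variance over the
histogram (256 bins) of in-mask pixels only, by explicit exhaustive search;
ties take the first maximum. The returned value is the bin boundary; a
constant slice raises a degenerate-slice signal and the caller skips the
slice (contributing no veins) with a log notice. The unit suite checks the
implementation against an exact-rational-arithmetic search on random
histograms.

**Binarize/invert.** The classical description inverts the image (veins
white) and thresholds; since 1−x > 1−t ⇔ x < t, the two steps are fused as
"vein = pixel strictly below threshold, inside the mask". A pixel exactly at
the threshold is background — a deterministic tie rule, unit-tested along
with the inversion equivalence.

**Top-hat.** White top-hat on the *binary* slice: input minus its opening
(erosion then dilation) with a 3×3 square element. On a binary image this
removes every connected region that contains a translate of the element —
exactly what eliminating the large inverted-background blobs requires —
while single pixels and thin lines survive. Erosion pads with background so
foreground touching the image border erodes; implementations differ on this,
so it is fixed here. An ambiguity exists in the source description between
applying the top-hat to the binary or to the grayscale slice; the binary
reading is the default, and a grayscale variant
(`SegmentationParams.tophat_grayscale`) is available without any claim of
fidelity.

**Intersection.** The processed SWI stack I₁ and MinIP stack I₂ intersect
with each hemisphere mask: V_left = I₁∩I₂∩H_left, V_right = I₁∩I₂∩H_right.
Containment (V ⊆ I₁, I₂, H), disjointness of the two sides, determinism of
reruns, and mirror equivariance are asserted as properties.

## Volumetry

ACVV = voxel count × voxel volume (mm³)/1000. DCVV = CDH − CNDH ≥ 0;
nDCVV = 100·DCVV/(CDH+CNDH), defined as 0 with side "tie" when both volumes
are equal (including both zero); ties are never assigned an arbitrary side,
and downstream classification treats them as "no asymmetry". nDCVV is scale
invariant. Group means of per-subject nDCVV are **not** the nDCVV of
group-mean volumes (the quantity is a ratio); the package always computes
nDCVV per subject before any averaging.

## Calibration and cohort statistics

`roc_youden` enumerates candidate cutoffs at the midpoints between
consecutive sorted unique scores plus ±∞, computes sensitivity/specificity
with the positivity rule *score strictly greater than cutoff*, and picks the
cutoff maximizing J = sens + spec − 1 (ties → smallest cutoff). The same
strict rule is used by `classify_vva`, so a score exactly at the cutoff is
negative in both places. Calibration is in-sample; no cross-validation is
claimed. Accuracy follows the identity acc = sens·prev + spec·(1−prev), with
a count-based variant for confusion tables.

Group comparisons use the pooled-variance Student t-test (recomputable from
printed mean/SD/n summaries; Welch available via flag), Pearson χ² without
continuity correction (a warning is logged when any expected count is below
5, where the asymptotic p-value is optimistic), and Pearson's r with the
t-based two-tailed p. These are thin wrappers over scipy.stats behind the
package's validation and error contracts.

## Phantom generator

The phantom emulates the image features the chain relies on, at the default
96×112×80 grid at 1 mm (≈0.9 M voxels, so a full generate+quantify cycle
takes about a second and large seed batches stay cheap):

- a mirror-symmetric ellipsoidal brain (semi-axes 38, 46, 32 mm) of
  homogeneous bright parenchyma (intensity 1.0) on a dark exterior (0.02);
- veins as smooth random 3D polyline tubes: a start point in a cortical
  shell (radial fraction 0.55–0.95, mimicking the cortical/subcortical
  predominance of the target veins), a persistent random walk of 2 mm steps,
  clipped at the brain surface and at the midline; tube radius uniform in
  0.6–1.5 mm (1–3 voxel diameters); intensity parenchyma×(1−contrast) with
  default contrast 0.6;
- a smooth multiplicative bias field (three-term low-frequency cosine
  mixture, amplitude 0.05) and additive Gaussian noise (SD 0.03 of
  parenchyma). Rician noise is not modelled: at these contrasts the
  Gaussian approximation is adequate and simpler;
- the MinIP companion derived with the standard projection (14 mm sliding
  slab).

Left and right vein counts are set independently (defaults 14/14), so the
ground-truth nDCVV is controllable through the load ratio; all randomness is
fixed by the seed (identical spec → bit-identical phantom). Veins that
cannot be placed within a bounded number of retries abort generation loudly.

What the phantom does **not** emulate: susceptibility physics (dipole
fields, echo-time and field-strength dependence of vein contrast), cortical
folding, deep grey nuclei, flow or calcification artifacts, and Rician noise
statistics. Passing the recovery tests therefore shows the chain measures
tubular hypointense structure and its lateralization correctly under
controlled conditions — not that it is robust to every artifact of clinical
SWI.

## What the recovery tests show

On clearly asymmetric phantoms (true nDCVV ≥ 15 %, contrast 0.6, noise SD
0.03) the measured dominant side matches the truth in ≥ 95 % of 40 seeded
phantoms, and mean measured nDCVV increases monotonically across load
ratios 1.0 / 1.5 / 2.0 with 20 seeds per level. Two facts matter when
reading these numbers. First, the slice-wise thresholding picks up noise
speckle in both hemispheres, so measured ACVV exceeds the true tube volume
and measured nDCVV is diluted toward zero relative to truth; the sign of
the asymmetry is far more stable than its magnitude. Second, at the
symmetric load ratio the expectation of *measured* |asymmetry| is positive
(it is a folded noisy difference), and with random radii the *true* nDCVV of
a "symmetric" phantom also has a positive mean, so adjacent level means
separate only a few percentage points — small seed batches can transiently
violate monotonicity even when the trend is real.

## Numerical and degenerate-input choices

- Tie at the binarization threshold → background; tie in hemispheric volume
  → side "tie"; tie in J → smallest cutoff. All deterministic.
- Empty or constant in-mask slices are skipped with a log notice, never
  fatal; an entirely empty brain mask is an error.
- Masks must be exactly 0/1; non-binary masks are rejected, not coerced.
- Volumes are written float32 (masks remain exact); spacing is preserved
  exactly through the affine.
- The whole pipeline is deterministic: identical inputs give bit-identical
  vein masks on reruns.

## Known limitations

- The deep-grey exclusion ellipsoid is geometric, not anatomical; for
  atlas-grade work supply an exclusion mask.
- Calibration is in-sample; reported sensitivity/specificity at the chosen
  cutoff are optimistic relative to out-of-sample use.
- The segmentation has no vesselness model; hypointense non-vein structure
  (microbleeds, calcifications, susceptibility artifacts at the cortical
  border) inside the analysis region would be counted as vein.
- Sliding-window MinIP and scanner block MinIP differ slightly near slab
  boundaries; both modes are provided because acquisition conventions vary.
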