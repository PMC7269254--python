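"""Synthetic SWI phantoms with ground-truth hemispheric vein masks.

A phantom emulates the appearance the segmentation chain relies on: a
mirror-symmetric ellipsoidal "brain" of bright homogeneous parenchyma on a
dark background, thin hypointense tubular veins (random smooth 3D polyline
tubes, ~1-3 voxels in diameter) placed predominantly in a cortical shell,
a smooth multiplicative bias field, and additive Gaussian noise.  The
left/right vein load is set independently, so the ground-truth hemispheric
asymmetry (nDCVV) is controllable; the MinIP companion volume is derived
with the same projection used for patient data.

It does not emulate susceptibility physics (dipole fields, echo-time
dependence), deep grey nuclei, or anatomical cortical folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import SlabSpec, compute_minip
from .volume_io import Volume, symmetric_affine

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "sweep_asymmetry"]


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the seed fixes all randomness."""

    shape: tuple[int, int, int] = (96, 112, 80)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_veins_left: int = 14
    n_veins_right: int = 14
    vein_radius_mm: tuple[float, float] = (0.6, 1.5)
    vein_contrast: float = 0.6      # fractional intensity drop inside veins
    bias_amplitude: float = 0.05    # fractional amplitude of the bias field
    noise_sd: float = 0.03          # of parenchyma intensity
    seed: int = 0
    brain_radii_mm: tuple[float, float, float] = (38.0, 46.0, 32.0)
    cortical_shell: tuple[float, float] = (0.55, 0.95)  # radial fraction band
    slab: SlabSpec = field(default_factory=SlabSpec)

    def __post_init__(self) -> None:
        if self.n_veins_left < 0 or self.n_veins_right < 0:
            raise ValueError("vein counts must be non-negative")
        if not (0 < self.vein_contrast <= 1):
            raise ValueError("vein contrast must be in (0, 1]")
        if self.vein_radius_mm[0] < min(self.spacing) / 2:
            raise ValueError("vein radius below half the voxel size is unresolvable")
        if self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("noise and bias amplitudes must be non-negative")


@dataclass
class PhantomTruth:
    """A generated phantom with its ground truth."""

    swi: Volume
    minip: Volume
    brain_mask: Volume
    vein_mask_left: np.ndarray
    vein_mask_right: np.ndarray
    true_acvv_left: float
    true_acvv_right: float
    true_ndcvv: float
    true_side: str  # "left" | "right" | "tie"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _ellipsoid_frac(p: np.ndarray, radii: np.ndarray) -> float:
    """Radial fraction of a world point w.r.t. the brain ellipsoid (1 = surface)."""
    return float(np.sqrt(np.sum((p / radii) ** 2)))


def _vein_polyline(rng: np.random.Generator, radii: np.ndarray, side: int,
                   shell: tuple[float, float]) -> np.ndarray | None:
    """Random smooth polyline inside one hemisphere of the brain ellipsoid.

    ``side`` is -1 for left (world x < 0), +1 for right.  Returns an array of
    points (n, 3) in world mm, or None if the walk came out too short.
    """
    for _ in range(20):
        direction = _unit(rng.normal(size=3))
        rho = rng.uniform(*shell)
        start = rho * radii * direction
        if side * start[0] > 3.0:
            break
    else:
        return None
    step = 2.0
    heading = _unit(rng.normal(size=3))
    pts = [start.copy()]
    p = start.copy()
    for _ in range(25):
        heading = _unit(heading + 0.35 * rng.normal(size=3))
        q = p + step * heading
        if _ellipsoid_frac(q, radii) > 0.98 or side * q[0] < 1.0:
            break
        pts.append(q.copy())
        p = q
    pts = np.asarray(pts)
    if len(pts) < 4:  # < ~6 mm of usable centerline
        return None
    return pts


def _rasterize_tube(mask: np.ndarray, pts: np.ndarray, radius: float,
                    affine_inv: np.ndarray, spacing: np.ndarray) -> None:
    """Mark all voxels whose center is within ``radius`` of the polyline."""
    shape = np.asarray(mask.shape)
    # sample the centerline densely relative to both radius and voxel size
    ds = min(0.3, radius / 2.0)
    samples = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        n = max(int(np.ceil(np.linalg.norm(seg) / ds)), 1)
        for t in range(1, n + 1):
            samples.append(a + seg * (t / n))
    half = np.ceil(radius / spacing).astype(int)
    for p in samples:
        ijk = (affine_inv[:3, :3] @ p + affine_inv[:3, 3])
        c = np.round(ijk).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half + 1, shape)
        if np.any(lo >= hi):
            continue
        gi, gj, gk = np.meshgrid(*(np.arange(lo[d], hi[d]) for d in range(3)),
                                 indexing="ij")
        d2 = (((gi - ijk[0]) * spacing[0]) ** 2
              + ((gj - ijk[1]) * spacing[1]) ** 2
              + ((gk - ijk[2]) * spacing[2]) ** 2)
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= radius ** 2


def _bias_field(shape, world, rng: np.random.Generator, amplitude: float) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * (low-order cosine mixture)."""
    if amplitude == 0:
        return np.ones(shape)
    b = np.zeros(shape)
    extent = np.array([w.max() - w.min() + 1e-9 for w in world])
    for _ in range(3):
        freq = rng.uniform(0.5, 1.5, size=3) / extent
        phase = rng.uniform(0, 2 * np.pi, size=3)
        term = np.ones(shape)
        for k in range(3):
            term = term * np.cos(2 * np.pi * freq[k] * world[k] + phase[k])
        b += term
    b /= max(np.abs(b).max(), 1e-9)
    return 1.0 + amplitude * b


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate one phantom; the same spec (same seed) is bit-reproducible."""
    rng = np.random.default_rng(spec.seed)
    affine = symmetric_affine(spec.shape, spec.spacing)
    grid = Volume(np.zeros(spec.shape), affine)
    world = [grid.world_coords(axis=k) for k in range(3)]
    radii = np.asarray(spec.brain_radii_mm, dtype=float)
    spacing = np.asarray(spec.spacing, dtype=float)

    dist2 = sum((world[k] / radii[k]) ** 2 for k in range(3))
    brain = dist2 <= 1.0

    affine_inv = np.linalg.inv(affine)
    vein_all = np.zeros(spec.shape, dtype=bool)
    for side, count in ((-1, spec.n_veins_left), (+1, spec.n_veins_right)):
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 50 * max(count, 1):
                raise RuntimeError(
                    f"could not place {count} veins on side {side} "
                    f"after {attempts} attempts")
            pts = _vein_polyline(rng, radii, side, spec.cortical_shell)
            if pts is None:
                continue
            radius = rng.uniform(*spec.vein_radius_mm)
            _rasterize_tube(vein_all, pts, radius, affine_inv, spacing)
            placed += 1

    vein_all &= brain
    left = vein_all & (world[0] < 0)
    right = vein_all & (world[0] > 0)

    parenchyma = 1.0
    img = np.where(brain, parenchyma, 0.02)
    img = np.where(vein_all, parenchyma * (1.0 - spec.vein_contrast), img)
    img *= _bias_field(spec.shape, world, rng, spec.bias_amplitude)
    img += rng.normal(0.0, spec.noise_sd * parenchyma, size=spec.shape)
    img = np.clip(img, 0.0, None)

    swi = Volume(img, affine)
    minip = compute_minip(swi, spec.slab)
    voxvol = float(np.prod(spacing)) / 1000.0
    a_l = float(left.sum()) * voxvol
    a_r = float(right.sum()) * voxvol
    total = a_l + a_r
    ndcvv = 100.0 * abs(a_l - a_r) / total if total > 0 else 0.0
    side = "left" if a_l > a_r else ("right" if a_r > a_l else "tie")
    return PhantomTruth(swi=swi, minip=minip,
                        brain_mask=Volume(brain.astype(np.uint8), affine),
                        vein_mask_left=left, vein_mask_right=right,
                        true_acvv_left=a_l, true_acvv_right=a_r,
                        true_ndcvv=ndcvv, true_side=side)


def sweep_asymmetry(base_spec: PhantomSpec, levels, seeds_per_level: int = 20,
                    seed_offset: int = 0) -> pd.DataFrame:
    """Run the full pipeline over a grid of left/right load ratios.

    Each level multiplies the left vein count by the given ratio (right count
    fixed at ``base_spec.n_veins_right``).  Returns one row per phantom with
    the true and measured nDCVV and whether the measured dominant side matches
    the truth (a measured tie counts as incorrect when the truth is
    asymmetric).
    """
    from .pipeline import quantify_phantom

    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least two asymmetry levels")
    rows = []
    for li, ratio in enumerate(levels):
        n_left = int(round(ratio * base_spec.n_veins_right))
        for k in range(seeds_per_level):
            seed = int(np.random.SeedSequence(
                entropy=[base_spec.seed + seed_offset, li, k]).generate_state(1)[0]
                % (2 ** 31))
            spec = replace(base_spec, n_veins_left=n_left, seed=seed)
            truth = generate_phantom(spec)
            result = quantify_phantom(truth)
            correct = (result.cdh_side == truth.true_side
                       if truth.true_side != "tie" else result.cdh_side == "tie")
            rows.append({"level": ratio, "seed": seed,
                         "true_ndcvv": truth.true_ndcvv,
                         "true_side": truth.true_side,
                         "measured_ndcvv": result.ndcvv,
                         "measured_side": result.cdh_side,
                         "side_correct": bool(correct)})
    return pd.DataFrame(rows)
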