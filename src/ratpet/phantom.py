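"""Synthetic rat-brain FDG-PET phantom: the pipeline's ground-truth test bed.

The digital anatomy is an ellipsoid composite in template-scale coordinates
(voxel [1 1 1.8] mm, the convention of the standard space): six gross
structures — olfactory bulb, cortex, hippocampi, mesencephalon, thalamus,
cerebellum — each split into left/right sub-labels (12 sub-labels, so label
merging is exercised), wrapped in a lower-intensity scalp shell, with two
eye blobs outside the cranium.  Subjects are produced by pushing the
ground-truth image through a random small affine plus a smooth random
cosine warp, optionally injecting a regional hypometabolism (an MCAO-like
fractional signal drop over the left lateral half of the cortex), then
blurring with the scanner PSF and adding Gaussian noise.

Everything is deterministic given (spec, seed): cohorts regenerate
bit-identically, and each subject carries its ground-truth transform for
recovery tests.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .registration import AffineParams, BasisWarp, Transform
from .volume import GridSpec, Volume

__all__ = ["PhantomSpec", "Subject", "make_ground_truth", "make_subject", "make_cohort"]

#: Structure intensities in arbitrary FDG-uptake units: gray-matter-rich
#: structures high, scalp well below brain, eyes intermediate.
DEFAULT_MEANS = {
    1: 90.0,   # olfactory bulb
    2: 100.0,  # cortex
    3: 95.0,   # hippocampi
    4: 92.0,   # mesencephalon
    5: 98.0,   # thalamus
    6: 96.0,   # cerebellum
}
SCALP_MEAN = 30.0
EYE_MEAN = 60.0


@dataclasses.dataclass
class PhantomSpec:
    """Study conditions of the synthetic cohort."""

    dims: tuple[int, int, int] = (64, 48, 40)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.8)
    structure_means: dict[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_MEANS)
    )
    scalp_mean: float = SCALP_MEAN
    eye_mean: float = EYE_MEAN
    # per-subject geometric variability
    max_translation_mm: float = 2.0
    max_rotation_rad: float = 0.05
    zoom_range: tuple[float, float] = (0.95, 1.05)
    max_shear: float = 0.02
    warp_amplitude_vox: float = 1.0
    warp_cutoff: int = 3
    # signal model
    psf_fwhm_mm: float = 1.5
    noise_sigma_frac: float = 0.05  # Gaussian sigma as fraction of brain mean
    # regional effect
    effect_structure: int = 2  # cortex
    effect_fraction: float = 0.0  # e.g. -0.2 for a 20% deficit
    seed: int = 0

    def __post_init__(self):
        if not -1.0 < self.effect_fraction < 1.0:
            raise ValueError("effect fraction must lie in (-1, 1)")

    @property
    def grid(self) -> GridSpec:
        lo = tuple(-(n / 2.0) * s for n, s in zip(self.dims, self.voxel_size))
        up = tuple((n / 2.0) * s for n, s in zip(self.dims, self.voxel_size))
        return GridSpec(lo, up, self.voxel_size)

    def normalized(self) -> "PhantomSpec":
        """Conditions of a cohort *after* spatial normalization.

        Voxel-wise statistics only ever see normalized scans, so cohorts fed
        to the GLM carry residual subvoxel misregistration (about half a
        voxel, the accuracy the registration itself achieves) rather than
        the full anatomical variability of raw scans.
        """
        return dataclasses.replace(
            self,
            max_translation_mm=0.5,
            max_rotation_rad=0.01,
            zoom_range=(0.99, 1.01),
            max_shear=0.005,
            warp_amplitude_vox=0.3,
        )


@dataclasses.dataclass
class Subject:
    """One synthetic scan plus the ground truth that produced it."""

    volume: Volume
    transform: Transform  # maps phantom-space mm -> subject-space mm sampling
    brain_mask: Volume  # subject-space brain support (pre-noise)
    effect_fraction: float


@dataclasses.dataclass
class GroundTruth:
    pet: Volume
    atlas: Volume
    brain_mask: Volume
    territory: Volume  # effect territory mask (left lateral cortex)
    spec: PhantomSpec


def _ellipsoid(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    acc = np.zeros(shape)
    for ax in range(3):
        acc += ((idx[ax] - center[ax]) / radii[ax]) ** 2
    return acc <= 1.0


def make_ground_truth(spec: PhantomSpec | None = None) -> GroundTruth:
    """Ellipsoid-composite anatomy: 12 sub-labels, scalp shell, eye blobs.

    Sub-label 2*s-1 / 2*s are the left / right halves of structure s, so a
    12 -> 6 merge table reconstructs the gross anatomy exactly.
    """
    spec = spec or PhantomSpec()
    nx, ny, nz = spec.dims
    shape = spec.dims
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    # physical-to-voxel anisotropy: radii below are in voxels of [1 1 1.8]
    rz = lambda mm: mm / spec.voxel_size[2]

    brain = _ellipsoid(shape, (cx, cy, cz), (0.30 * nx, 0.28 * ny, rz(0.38 * nz * 1.8)))
    scalp_outer = _ellipsoid(shape, (cx, cy, cz), (0.36 * nx, 0.34 * ny, rz(0.45 * nz * 1.8)))

    struct = np.zeros(shape, dtype=np.int32)
    struct[brain] = 2  # cortex is the default brain tissue

    olf = _ellipsoid(shape, (cx, cy, cz + 0.33 * nz), (0.10 * nx, 0.10 * ny, rz(0.10 * nz * 1.8)))
    cereb = _ellipsoid(shape, (cx, cy, cz - 0.30 * nz), (0.16 * nx, 0.16 * ny, rz(0.12 * nz * 1.8)))
    thal = _ellipsoid(shape, (cx, cy + 0.04 * ny, cz - 0.02 * nz), (0.10 * nx, 0.10 * ny, rz(0.08 * nz * 1.8)))
    mes = _ellipsoid(shape, (cx, cy + 0.02 * ny, cz - 0.16 * nz), (0.09 * nx, 0.09 * ny, rz(0.07 * nz * 1.8)))
    hip_l = _ellipsoid(shape, (cx - 0.12 * nx, cy - 0.05 * ny, cz + 0.02 * nz), (0.06 * nx, 0.07 * ny, rz(0.07 * nz * 1.8)))
    hip_r = _ellipsoid(shape, (cx + 0.12 * nx, cy - 0.05 * ny, cz + 0.02 * nz), (0.06 * nx, 0.07 * ny, rz(0.07 * nz * 1.8)))

    struct[olf & brain] = 1
    struct[cereb & brain] = 6
    struct[mes & brain] = 4
    struct[thal & brain] = 5
    struct[(hip_l | hip_r) & brain] = 3
    # olfactory bulb protrudes beyond the main ellipsoid
    struct[olf & scalp_outer] = 1

    brain_support = struct > 0

    atlas = np.zeros(shape, dtype=np.int32)
    left = np.indices(shape)[0] < cx
    for s in range(1, 7):
        sel = struct == s
        atlas[sel & left] = 2 * s - 1
        atlas[sel & ~left] = 2 * s

    pet = np.zeros(shape)
    for s, mean in spec.structure_means.items():
        pet[struct == s] = mean
    scalp = scalp_outer & ~brain_support
    pet[scalp] = spec.scalp_mean

    eye_z = cz + 0.36 * nz
    for sx in (-1, +1):
        eye = _ellipsoid(shape, (cx + sx * 0.22 * nx, cy + 0.10 * ny, eye_z),
                         (0.05 * nx, 0.06 * ny, rz(0.05 * nz * 1.8)))
        eye &= ~brain_support
        pet[eye] = spec.eye_mean

    # MCAO-like territory: left lateral half of the cortex
    cortex = struct == 2
    territory = cortex & (np.indices(shape)[0] < cx - 0.10 * nx)

    touches_border = (
        brain_support[[0, -1], :, :].any()
        or brain_support[:, [0, -1], :].any()
        or brain_support[:, :, [0, -1]].any()
    )
    if not brain_support[1:-1, 1:-1, 1:-1].any() or touches_border:
        raise ValueError("phantom anatomy exceeds the grid; enlarge dims or voxel size")

    grid = spec.grid
    mk = lambda d: Volume(d.astype(float) if d.dtype == bool else d,
                          voxel_size=spec.voxel_size, origin=grid.origin, space="template")
    return GroundTruth(
        pet=mk(pet),
        atlas=mk(atlas.astype(float)),
        brain_mask=mk(brain_support),
        territory=mk(territory),
        spec=spec,
    )


def sublabel_mapping() -> dict[int, int]:
    """The phantom's 12 sub-label -> 6 structure merge table."""
    return {2 * s - 1 + off: s for s in range(1, 7) for off in (0, 1)}


def _random_transform(spec: PhantomSpec, rng: np.random.Generator, grid: GridSpec) -> Transform:
    t = rng.uniform(-spec.max_translation_mm, spec.max_translation_mm, 3)
    r = rng.uniform(-spec.max_rotation_rad, spec.max_rotation_rad, 3)
    z = rng.uniform(*spec.zoom_range, 3)
    h = rng.uniform(-spec.max_shear, spec.max_shear, 3)
    aff = AffineParams(tuple(t), tuple(r), tuple(z), tuple(h))
    warp = None
    if spec.warp_amplitude_vox > 0:
        k = spec.warp_cutoff
        C = rng.standard_normal((3, k, k, k))
        # basis is orthonormal on the grid, so RMS displacement per axis is
        # sqrt(sum C^2 / N); scale to the requested amplitude in mm
        n_vox = float(np.prod(grid.dims))
        amp_mm = spec.warp_amplitude_vox * float(np.mean(spec.voxel_size))
        rms = np.sqrt(np.sum(C**2) / (3.0 * n_vox))
        C *= amp_mm / max(rms, 1e-12)
        warp = BasisWarp(C, grid)
    return Transform(affine=aff, warp=warp)


def make_subject(gt: GroundTruth, spec: PhantomSpec | None = None, subject_seed: int = 0) -> Subject:
    """Deform, inject the effect, blur with the PSF, add noise."""
    spec = spec or gt.spec
    rng = np.random.default_rng(subject_seed)
    grid = spec.grid
    transform = _random_transform(spec, rng, grid)

    pet = np.asarray(gt.pet.data, float)
    if spec.effect_fraction != 0.0:
        pet = pet.copy()
        sel = np.asarray(gt.territory.data) != 0
        pet[sel] *= 1.0 + spec.effect_fraction

    from .volume import resample

    src = Volume(pet, gt.pet.voxel_size, gt.pet.origin, gt.pet.space)
    moved = resample(src, grid, transform, interpolation="trilinear")
    moved_mask = resample(gt.brain_mask, grid, transform, interpolation="nearest")

    sigma_vox = spec.psf_fwhm_mm / np.sqrt(8 * np.log(2)) / np.asarray(spec.voxel_size)
    blurred = ndimage.gaussian_filter(moved.data, sigma=tuple(sigma_vox), mode="constant")

    brain_mean = float(np.asarray(gt.pet.data)[np.asarray(gt.brain_mask.data) != 0].mean())
    noise = rng.standard_normal(blurred.shape) * (spec.noise_sigma_frac * brain_mean)
    data = blurred + noise if spec.noise_sigma_frac > 0 else blurred

    vol = Volume(data, voxel_size=spec.voxel_size, origin=grid.origin, space="native")
    return Subject(
        volume=vol,
        transform=transform,
        brain_mask=moved_mask,
        effect_fraction=spec.effect_fraction,
    )


def make_cohort(
    spec: PhantomSpec | None = None,
    n_a: int = 9,
    n_b: int = 8,
    effect_in_a: float = 0.0,
    seed: int | None = None,
) -> tuple[list[Subject], list[Subject], GroundTruth]:
    """Two reproducible groups sharing one anatomy; group A may carry the effect.

    The default sizes mirror a stroke-model study: 9 occluded animals
    versus 8 healthy controls.  Subject seeds are drawn from the cohort
    seed, so (spec, seed) fully determines every voxel.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    spec = spec or PhantomSpec()
    seed = spec.seed if seed is None else seed
    gt = make_ground_truth(spec)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_a + n_b)]

    spec_a = dataclasses.replace(spec, effect_fraction=effect_in_a)
    group_a = [make_subject(gt, spec_a, child_seeds[i]) for i in range(n_a)]
    group_b = [make_subject(gt, spec, child_seeds[n_a + i]) for i in range(n_b)]
    return group_a, group_b, gt
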