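"""Recursive register-average construction of the population template.

One cohort scan seeds the target; every original scan is registered
(affine + optional cosine-basis warp) to the current target, the registered
scans are averaged into a new target, and the loop repeats until the mean
squared residual difference between successive targets stabilizes.  Always
re-registering the *original* scans (never previously warped copies) avoids
compounding interpolation blur across rounds.

Two convergence statistics are logged each round for a pair of old/new
targets f and g with n voxels:

    d   = (1/n) sum_i (f_i - g_i)^2          (intensity^2 units)
    rel = sum_i (f_i - g_i)^2 / sum_i f_i^2  (unitless)

The stopping rule compares the scale-invariant ``rel`` against the
threshold (default 5%); ``d`` is kept alongside so either convention can be
audited.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .registration import RegistrationError, Transform, estimate_affine, estimate_nonlinear
from .volume import GridSpec, Volume, resample

__all__ = ["ConvergenceRecord", "TemplateSet", "mean_squared_residual", "build_average_template"]


@dataclasses.dataclass(frozen=True)
class ConvergenceRecord:
    iteration: int
    d: float
    rel: float


@dataclasses.dataclass
class TemplateSet:
    """Template with extracranial tissue, canonical brain, intracranial mask.

    All three share one grid, voxel size and origin (the dorsal third
    ventricle, D3V); the canonical brain equals the template under the mask.
    """

    template: Volume
    canonical: Volume
    mask: Volume

    def __post_init__(self):
        shapes = {self.template.shape, self.canonical.shape, self.mask.shape}
        if len(shapes) != 1:
            raise ValueError(f"template set grids differ: {shapes}")
        if self.template.voxel_size != self.canonical.voxel_size or (
            self.template.voxel_size != self.mask.voxel_size
        ):
            raise ValueError("template set voxel sizes differ")
        if self.template.origin != self.mask.origin or self.template.origin != self.canonical.origin:
            raise ValueError("template set origins differ")
        if not np.all(np.isin(np.unique(self.mask.data), (0, 1))):
            raise ValueError("mask must be binary")

    @property
    def grid(self) -> GridSpec:
        return GridSpec.from_volume(self.template)


def mean_squared_residual(f: Volume, g: Volume) -> tuple[float, float]:
    """(d, rel) between an old target f and a new target g on one grid."""
    if f.shape != g.shape:
        raise ValueError(f"grid mismatch: {f.shape} vs {g.shape}")
    fd = np.asarray(f.data, float)
    gd = np.asarray(g.data, float)
    sq = float(np.sum((fd - gd) ** 2))
    n = fd.size
    denom = float(np.sum(fd**2))
    if denom == 0.0:
        if sq == 0.0:
            return 0.0, 0.0
        raise ValueError("relative residual undefined: old target is identically zero")
    return sq / n, sq / denom


def build_average_template(
    scans: list[Volume],
    initial_index: int = 0,
    threshold: float = 0.05,
    max_iter: int = 10,
    nonlinear: bool = True,
    cutoff: int = 4,
    lam: float = 1.0,
) -> tuple[Volume, list[ConvergenceRecord]]:
    """Iterate register -> average -> residual until ``rel`` < threshold.

    Returns the final average target and the full convergence trace.  The
    initial target is the caller-chosen cohort scan (``initial_index``); any
    per-scan registration failure aborts with the failing scan identified.
    """
    if len(scans) < 2:
        raise ValueError("need at least 2 scans to build a template")
    if not 0 <= initial_index < len(scans):
        raise IndexError(f"initial_index {initial_index} out of range for {len(scans)} scans")

    target = scans[initial_index].copy()
    grid = GridSpec.from_volume(target)
    trace: list[ConvergenceRecord] = []

    for k in range(1, max_iter + 1):
        registered = []
        for idx, scan in enumerate(scans):
            try:
                aff = estimate_affine(scan, target)
                if nonlinear:
                    t = estimate_nonlinear(scan, target, init=aff, cutoff=cutoff, lam=lam)
                else:
                    t = Transform(affine=aff)
                registered.append(resample(scan, grid, t, interpolation="trilinear"))
            except RegistrationError as exc:
                raise RegistrationError(f"registration of scan {idx} failed: {exc}") from exc
        new_data = np.mean([r.data for r in registered], axis=0)
        new_target = target.copy(data=new_data)
        d, rel = mean_squared_residual(target, new_target)
        trace.append(ConvergenceRecord(k, d, rel))
        target = new_target
        if rel < threshold:
            break
    return target, trace
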