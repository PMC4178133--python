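"""Voxel-wise two-sample statistics with family-wise-error control.

The group comparison follows the statistical parametric mapping recipe:
smooth the normalized scans, proportionally scale each scan so its in-mask
mean equals a grand mean (removing global tracer-dose confounds), fit a
voxel-wise pooled-variance two-sample t statistic, estimate the residual
field's smoothness (FWHM per axis), and threshold at a family-wise-error
corrected height using the expected Euler characteristic of a T random
field (Worsley's resel-based formula), optionally cross-checked by a
max-t permutation scheme.  Suprathreshold voxels are grouped into
connected clusters, small clusters are dropped, and each surviving cluster
is reported with its extent K_E, corrected peak p-value, peak T and Z, and
peak coordinates in Paxinos mm.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy import ndimage, special
from scipy import stats as sps

from .volume import PaxinosAxes, Volume, voxel_to_paxinos

__all__ = [
    "DesignMatrix",
    "SmoothnessEstimate",
    "StatResult",
    "proportional_scaling",
    "fit_two_sample_t",
    "t_to_z",
    "estimate_smoothness",
    "fwe_threshold",
    "expected_euler_characteristic",
    "cluster_table",
    "two_sample_analysis",
]

_Z_CLAMP = 38.0  # |z| bound where the normal tail underflows float64


@dataclasses.dataclass
class DesignMatrix:
    """Two-column group-indicator design with a zero-sum contrast."""

    matrix: np.ndarray
    contrast: tuple[float, float] = (1.0, -1.0)

    def __post_init__(self):
        X = np.asarray(self.matrix, float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("design must be subjects x 2 group indicators")
        if not np.all(np.isin(X, (0.0, 1.0))) or not np.all(X.sum(axis=1) == 1):
            raise ValueError("each subject must belong to exactly one group")
        if abs(sum(self.contrast)) > 1e-12:
            raise ValueError("group-difference contrast must sum to 0")
        self.matrix = X

    @classmethod
    def two_group(cls, n_a: int, n_b: int) -> "DesignMatrix":
        X = np.zeros((n_a + n_b, 2))
        X[:n_a, 0] = 1.0
        X[n_a:, 1] = 1.0
        return cls(X)


@dataclasses.dataclass(frozen=True)
class SmoothnessEstimate:
    """Residual-field FWHM per axis (mm), resel counts and search size."""

    fwhm_mm: tuple[float, float, float]
    resels: tuple[float, float, float, float]  # R0..R3
    n_voxels: int

    @property
    def resel_count(self) -> float:
        return self.resels[3]


@dataclasses.dataclass
class StatResult:
    tmap: Volume
    df: int
    valid_mask: np.ndarray
    smoothness: SmoothnessEstimate | None = None
    threshold: float | None = None
    clusters: pd.DataFrame | None = None
    residuals: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Scaling and the t map


def proportional_scaling(scans: list[Volume], mask: Volume, grand_mean: float = 50.0) -> list[Volume]:
    """Scale each scan so its in-mask mean equals the grand mean."""
    m = np.asarray(mask.data) != 0
    if not m.any():
        raise ValueError("mask is empty")
    out = []
    for i, v in enumerate(scans):
        mean = float(np.asarray(v.data)[m].mean())
        if mean == 0.0:
            raise ValueError(f"scan {i} has zero in-mask mean; cannot proportionally scale")
        out.append(v.copy(data=np.asarray(v.data, float) * (grand_mean / mean)))
    return out


def fit_two_sample_t(group_a: list[Volume], group_b: list[Volume], mask: Volume) -> StatResult:
    """Pooled-variance two-sample t (A - B) at every in-mask voxel.

    Zero-variance voxels get t = 0 and are excluded from the search volume
    (``valid_mask``); df = nA + nB - 2.
    """
    n_a, n_b = len(group_a), len(group_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    shapes = {v.shape for v in group_a + group_b} | {mask.shape}
    if len(shapes) != 1:
        raise ValueError(f"scans and mask must share one grid, got {shapes}")
    A = np.stack([np.asarray(v.data, float) for v in group_a])
    B = np.stack([np.asarray(v.data, float) for v in group_b])
    m = np.asarray(mask.data) != 0

    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    ss_a = ((A - mean_a) ** 2).sum(axis=0)
    ss_b = ((B - mean_b) ** 2).sum(axis=0)
    df = n_a + n_b - 2
    pooled = (ss_a + ss_b) / df
    se = np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    valid = m & (se > 0)
    t = np.where(valid, t, 0.0)

    residuals = np.concatenate([A - mean_a, B - mean_b], axis=0)
    ref = group_a[0]
    tvol = Volume(t, voxel_size=ref.voxel_size, origin=ref.origin, space=ref.space)
    return StatResult(tmap=tvol, df=df, valid_mask=valid, residuals=residuals)


def t_to_z(t, df: int):
    """Map a t value to the standard-normal deviate with equal tail mass.

    Computed through log tail probabilities so extreme t values do not
    saturate; the result is clamped to +/-38 where the double-precision
    normal tail underflows.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t = np.asarray(t, float)
    sign = np.sign(t)
    logp = sps.t.logsf(np.abs(t), df)  # upper-tail log p of |t|
    z = -special.ndtri_exp(logp)  # positive z with the same upper tail
    z = np.clip(z, -_Z_CLAMP, _Z_CLAMP)
    out = sign * z
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Smoothness and resels


def estimate_smoothness(residuals, mask) -> SmoothnessEstimate:
    """Per-axis FWHM of the residual field plus lattice resel counts.

    Residuals are variance-normalized per voxel; the variance of their
    first differences along each axis estimates the derivative variance
    lambda of a unit-variance field, and FWHM = sqrt(4 ln 2 / lambda) in
    voxel units (exact for a Gaussian autocorrelation).
    """
    if isinstance(residuals, list):
        ref = residuals[0]
        voxel_size = ref.voxel_size
        R = np.stack([np.asarray(v.data, float) for v in residuals])
    else:
        R = np.asarray(residuals, float)
        voxel_size = mask.voxel_size if isinstance(mask, Volume) else (1.0, 1.0, 1.0)
    if R.shape[0] < 3:
        raise ValueError("need at least 3 residual volumes to estimate smoothness")
    m = (np.asarray(mask.data) if isinstance(mask, Volume) else np.asarray(mask)) != 0

    sd = R.std(axis=0, ddof=0)
    ok = m & (sd > 0)
    if not ok.any():
        raise ValueError("residuals are constant inside the mask; smoothness undefined")
    U = np.where(ok, R / np.where(sd > 0, sd, 1.0), np.nan)

    fwhm_vox = []
    for ax in range(3):
        d = np.diff(U, axis=ax + 1)
        pair_ok = ~np.isnan(d)
        if pair_ok.sum() == 0:
            fwhm_vox.append(float(U.shape[ax + 1]))
            continue
        lam = float(np.nanmean(d**2))
        if lam <= 0:
            fwhm_vox.append(float(U.shape[ax + 1]))
        else:
            fwhm_vox.append(float(np.sqrt(4.0 * np.log(2.0) / lam)))

    fwhm_mm = tuple(f * s for f, s in zip(fwhm_vox, voxel_size))
    resels = _lattice_resels(m, fwhm_vox)
    return SmoothnessEstimate(fwhm_mm=fwhm_mm, resels=resels, n_voxels=int(m.sum()))


def _lattice_resels(mask: np.ndarray, fwhm_vox) -> tuple[float, float, float, float]:
    """Resel counts R0..R3 of a voxel mask from its cubical-complex counts.

    P vertices, E edges, F faces and C cubes of the complex give, with
    r_a = 1/FWHM_a in voxels (Worsley's lattice formulae):

        R0 = P - Ex - Ey - Ez + Fxy + Fxz + Fyz - C        (Euler char.)
        R1 = (Ex-Fxy-Fxz+C) rx + (Ey-Fxy-Fyz+C) ry + (Ez-Fxz-Fyz+C) rz
        R2 = (Fxy-C) rx ry + (Fxz-C) rx rz + (Fyz-C) ry rz
        R3 = C rx ry rz

    For a full cuboid these reduce to 1, a+b+c, ab+ac+bc, abc with side
    lengths in FWHM units.
    """
    m = mask.astype(bool)
    P = int(m.sum())
    Ex = int((m[:-1] & m[1:]).sum())
    Ey = int((m[:, :-1] & m[:, 1:]).sum())
    Ez = int((m[:, :, :-1] & m[:, :, 1:]).sum())
    Fxy = int((m[:-1, :-1] & m[1:, :-1] & m[:-1, 1:] & m[1:, 1:]).sum())
    Fxz = int((m[:-1, :, :-1] & m[1:, :, :-1] & m[:-1, :, 1:] & m[1:, :, 1:]).sum())
    Fyz = int((m[:, :-1, :-1] & m[:, 1:, :-1] & m[:, :-1, 1:] & m[:, 1:, 1:]).sum())
    C = int(
        (
            m[:-1, :-1, :-1] & m[1:, :-1, :-1] & m[:-1, 1:, :-1] & m[:-1, :-1, 1:]
            & m[1:, 1:, :-1] & m[1:, :-1, 1:] & m[:-1, 1:, 1:] & m[1:, 1:, 1:]
        ).sum()
    )
    rx, ry, rz = (1.0 / f for f in fwhm_vox)
    r0 = P - Ex - Ey - Ez + Fxy + Fxz + Fyz - C
    r1 = (Ex - Fxy - Fxz + C) * rx + (Ey - Fxy - Fyz + C) * ry + (Ez - Fxz - Fyz + C) * rz
    r2 = (Fxy - C) * rx * ry + (Fxz - C) * rx * rz + (Fyz - C) * ry * rz
    r3 = C * rx * ry * rz
    return (float(r0), float(r1), float(r2), float(r3))


# ---------------------------------------------------------------------------
# FWE thresholds


def _ec_densities_t(t: float, df: int) -> tuple[float, float, float, float]:
    """Euler-characteristic densities rho_0..rho_3 of a T field (Worsley)."""
    t = float(t)
    nu = float(df)
    a = (1.0 + t * t / nu) ** (-0.5 * (nu - 1.0))
    ln2_4 = 4.0 * np.log(2.0)
    rho0 = float(sps.t.sf(t, df))
    rho1 = np.sqrt(ln2_4) / (2.0 * np.pi) * a
    lgam = special.gammaln(0.5 * (nu + 1.0)) - special.gammaln(0.5 * nu)
    c2 = np.exp(lgam) / np.sqrt(0.5 * nu)
    rho2 = ln2_4 / (2.0 * np.pi) ** 1.5 * c2 * t * a
    rho3 = ln2_4**1.5 / (2.0 * np.pi) ** 2 * ((nu - 1.0) / nu * t * t - 1.0) * a
    return rho0, float(rho1), float(rho2), float(rho3)


def expected_euler_characteristic(t: float, s: SmoothnessEstimate, df: int) -> float:
    """Expected EC of the suprathreshold T field — the corrected p at height t."""
    rho = _ec_densities_t(t, df)
    return float(sum(R * r for R, r in zip(s.resels, rho)))


def fwe_threshold(
    s: SmoothnessEstimate,
    df: int,
    alpha: float = 0.05,
    method: str = "rft",
    permutation_samples: np.ndarray | None = None,
) -> float:
    """Height threshold controlling the family-wise error at ``alpha``.

    ``rft``: smallest t whose expected Euler characteristic is <= alpha
    (random-field theory), capped at the Bonferroni threshold — at low df or
    low smoothness the EC bound can exceed Bonferroni, so the sharper of the
    two valid bounds is used, as statistical parametric mapping does;
    ``bonferroni``: alpha split over the valid voxels; ``permutation``: the
    (1-alpha) quantile of a caller-supplied max-t null distribution (see
    :func:`permutation_max_t`).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    bonf = float(sps.t.isf(alpha / max(s.n_voxels, 1), df))
    if method == "bonferroni":
        return bonf
    if method == "permutation":
        if permutation_samples is None:
            raise ValueError("permutation method needs the max-t null samples")
        return float(np.quantile(permutation_samples, 1.0 - alpha))
    if method != "rft":
        raise ValueError(f"unknown FWE method {method!r}")
    if df < 3:
        raise ValueError("df too small for the T-field EC expansion; use permutation")

    lo = float(sps.t.isf(alpha, df))  # resels -> 0 limit: uncorrected threshold
    f = lambda t: expected_euler_characteristic(t, s, df) - alpha
    if f(lo) <= 0:
        return min(lo, bonf)
    hi = lo + 1.0
    while f(hi) > 0 and hi < max(1e3, 4.0 * bonf):
        hi *= 2.0
    if f(hi) > 0:
        # heavy low-df tails: the EC curve never crosses alpha below the cap
        return bonf
    from scipy.optimize import brentq

    return min(float(brentq(f, lo, hi, xtol=1e-8)), bonf)


def permutation_max_t(
    group_a: list[Volume],
    group_b: list[Volume],
    mask: Volume,
    n_permutations: int = 500,
    rng: np.random.Generator | int | None = 0,
) -> np.ndarray:
    """Max-t null distribution over two-sample group-label permutations.

    Uses all distinct relabellings when there are fewer than
    ``n_permutations``, otherwise a seeded random subset; the observed
    labelling is always included (guaranteeing valid p-values).
    """
    rng = np.random.default_rng(rng)
    n_a, n_b = len(group_a), len(group_b)
    n = n_a + n_b
    data = np.stack([np.asarray(v.data, float) for v in group_a + group_b])
    m = np.asarray(mask.data) != 0
    X = data[:, m]

    from math import comb

    if comb(n, n_a) <= n_permutations:
        picks = [np.asarray(c) for c in itertools.combinations(range(n), n_a)]
    else:
        picks = [np.arange(n_a)]
        while len(picks) < n_permutations:
            picks.append(np.sort(rng.choice(n, n_a, replace=False)))

    df = n - 2
    out = np.empty(len(picks))
    idx_all = np.arange(n)
    for i, ia in enumerate(picks):
        ib = np.setdiff1d(idx_all, ia, assume_unique=True)
        A, B = X[ia], X[ib]
        va = A.var(axis=0, ddof=0) * n_a
        vb = B.var(axis=0, ddof=0) * n_b
        se = np.sqrt((va + vb) / df * (1.0 / n_a + 1.0 / n_b))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (A.mean(axis=0) - B.mean(axis=0)) / se
        t = np.where(se > 0, t, 0.0)
        out[i] = t.max()
    return out


# ---------------------------------------------------------------------------
# Cluster reporting


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def cluster_table(
    result: StatResult,
    threshold: float,
    extent: int = 50,
    connectivity: int = 18,
    axes: PaxinosAxes = PaxinosAxes(),
    min_peak_distance_mm: float = 8.0,
    max_peaks_per_cluster: int = 3,
) -> pd.DataFrame:
    """Suprathreshold clusters with extent and peak statistics.

    Clusters are connected components of {t > threshold} among valid voxels
    (18-connectivity by default), dropped below ``extent`` voxels, numbered
    by descending extent; within a cluster, secondary maxima at least
    ``min_peak_distance_mm`` from every stronger reported peak appear as
    extra rows sharing the cluster number.  Peak p-values are
    FWE-corrected (expected EC at the peak height, clipped to 1).
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be 6, 18 or 26")
    t = np.asarray(result.tmap.data)
    supra = (t > threshold) & result.valid_mask
    cols = ["cluster", "K_E", "P_FWE_corr", "Max_T", "Max_Z", "x", "y", "z"]
    if not supra.any():
        return pd.DataFrame(columns=cols)

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    labels, n_lab = ndimage.label(supra, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    keep = [(int(sz), lab) for lab, sz in zip(range(1, n_lab + 1), sizes) if sz >= extent]
    keep.sort(key=lambda p: (-p[0], p[1]))

    vs = np.asarray(result.tmap.voxel_size)
    rows = []
    for number, (k_e, lab) in enumerate(keep, start=1):
        sel = labels == lab
        coords = np.argwhere(sel)
        tv = t[sel]
        order = np.argsort(tv)[::-1]
        peaks: list[np.ndarray] = []
        for oi in order:
            c = coords[oi]
            if len(peaks) >= max_peaks_per_cluster:
                break
            if peaks and min(
                np.linalg.norm((c - p) * vs) for p in peaks
            ) < min_peak_distance_mm:
                continue
            if peaks and not _is_local_max(t, c, structure):
                continue
            peaks.append(c)
        for c in peaks:
            tpk = float(t[tuple(c)])
            p_fwe = (
                min(1.0, expected_euler_characteristic(tpk, result.smoothness, result.df))
                if result.smoothness is not None
                else np.nan
            )
            x, y, z = voxel_to_paxinos(result.tmap, c, axes=axes)
            rows.append(
                dict(
                    cluster=number, K_E=k_e, P_FWE_corr=p_fwe,
                    Max_T=tpk, Max_Z=float(t_to_z(tpk, result.df)),
                    x=x, y=y, z=z,
                )
            )
    return pd.DataFrame(rows, columns=cols)


def _is_local_max(t: np.ndarray, c: np.ndarray, structure: np.ndarray) -> bool:
    sl = tuple(slice(max(i - 1, 0), i + 2) for i in c)
    return t[tuple(c)] >= t[sl].max()


# ---------------------------------------------------------------------------
# The full two-sample pipeline


def two_sample_analysis(
    group_a: list[Volume],
    group_b: list[Volume],
    mask: Volume,
    smooth_fwhm=(2.0, 2.0, 4.0),
    grand_mean: float = 50.0,
    alpha: float = 0.05,
    extent: int = 50,
    method: str = "rft",
    connectivity: int = 18,
    axes: PaxinosAxes = PaxinosAxes(),
    contrast: str = "B<A",
    permutation_kwargs: dict | None = None,
) -> StatResult:
    """Smooth -> proportional scaling -> two-sample t -> FWE clusters.

    ``contrast='B<A'`` tests for lower signal in group B (the t map is
    A - B, thresholded in its positive tail); ``'A<B'`` flips the sign.
    """
    from .atlas import smooth_gaussian

    def prep(vols):
        return [smooth_gaussian(v, smooth_fwhm) for v in vols]

    a = proportional_scaling(prep(group_a), mask, grand_mean)
    b = proportional_scaling(prep(group_b), mask, grand_mean)
    if contrast == "A<B":
        a, b = b, a
    elif contrast != "B<A":
        raise ValueError("contrast must be 'B<A' or 'A<B'")

    res = fit_two_sample_t(a, b, mask)
    res.smoothness = estimate_smoothness(res.residuals, Volume(
        res.valid_mask.astype(float), mask.voxel_size, mask.origin, mask.space
    ))
    if method == "permutation":
        kw = dict(permutation_kwargs or {})
        samples = permutation_max_t(a, b, mask, **kw)
        res.threshold = fwe_threshold(
            res.smoothness, res.df, alpha, "permutation", permutation_samples=samples
        )
    else:
        res.threshold = fwe_threshold(res.smoothness, res.df, alpha, method)
    res.clusters = cluster_table(res, res.threshold, extent=extent, connectivity=connectivity, axes=axes)
    return res
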