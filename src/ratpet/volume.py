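"""Volume data model, Analyze/NIfTI I/O, sampling grids and Paxinos coordinates.

A :class:`Volume` is the currency of the whole pipeline: a 3-D scalar grid
with a physical voxel size in mm, an ``origin`` voxel index marking where the
coordinate origin sits (the dorsal third ventricle, D3V, for the template
set), and a ``space`` tag.  Arrays are stored in Paxinos axis order:

* axis 0 — x, left–right; increasing index is to the animal's right, so the
  reported x coordinate is negative on the left of the midline;
* axis 1 — y, dorso-ventral; increasing index is ventral (positive y);
* axis 2 — z, rostro-caudal; increasing index is toward the olfactory bulb
  (positive z), decreasing toward the cerebellum.

The rostro-caudal coordinate is conventionally reported relative to bregma
while the template origin sits at D3V; a configurable ``z_bregma_offset``
(mm, default 0) bridges the two conventions when reporting coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "GridSpec",
    "PaxinosAxes",
    "STANDARD_GRID",
    "SHEAR_DIMS",
    "read_volume",
    "write_volume",
    "scale_voxel_header",
    "grid_dims",
    "voxel_to_paxinos",
    "paxinos_to_voxel",
    "resample",
]


@dataclasses.dataclass
class Volume:
    """3-D intensity grid with voxel size (mm), origin voxel and space tag."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    space: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 and self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if self.data.ndim == 4:
            raise ValueError("4D volumes are not supported (dynamic PET is out of scope)")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive numbers, got {vs}")
        self.voxel_size = vs
        self.origin = tuple(float(o) for o in self.origin)
        if self.space not in ("native", "template", "paxinos"):
            raise ValueError(f"unknown space tag {self.space!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def copy(self, data: np.ndarray | None = None, **overrides) -> "Volume":
        """Return a copy, optionally replacing the data grid or metadata."""
        kw = dict(
            data=self.data.copy() if data is None else data,
            voxel_size=self.voxel_size,
            origin=self.origin,
            space=self.space,
        )
        kw.update(overrides)
        return Volume(**kw)

    def assert_no_nan(self) -> "Volume":
        if np.isnan(self.data).any():
            raise ValueError("volume contains NaN; background must be 0")
        return self


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """A physical bounding box [lower, upper) mm discretised at voxel_size mm.

    Half-open convention: dims = (upper - lower) / voxel_size exactly, and
    the voxel with index i sits at lower + i * voxel_size.  The standard
    template-space grid [-150 -180 -126; 150 60 72] at [1 1 1.8] therefore
    has 300 x 240 x 110 voxels with an integer origin index.
    """

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, float)
        up = np.asarray(self.upper, float)
        vs = np.asarray(self.voxel_size, float)
        if np.any(vs <= 0):
            raise ValueError("voxel sizes must be positive")
        if np.any(up <= lo):
            raise ValueError("upper must exceed lower componentwise")
        ratio = (up - lo) / vs
        if np.any(np.abs(ratio - np.round(ratio)) > 1e-6 * np.maximum(ratio, 1.0)):
            raise ValueError(
                f"box extent {tuple(up - lo)} is not an integer multiple of voxel size {tuple(vs)}"
            )

    @property
    def dims(self) -> tuple[int, int, int]:
        return grid_dims(self)

    @property
    def origin(self) -> tuple[float, float, float]:
        """Voxel index (possibly fractional) of the mm origin."""
        lo = np.asarray(self.lower, float)
        vs = np.asarray(self.voxel_size, float)
        return tuple(-lo / vs)

    def empty_volume(self, space: str = "template") -> Volume:
        return Volume(
            np.zeros(self.dims, dtype=np.float64),
            voxel_size=self.voxel_size,
            origin=self.origin,
            space=space,
        )

    @classmethod
    def from_volume(cls, v: Volume) -> "GridSpec":
        lo = tuple(-o * s for o, s in zip(v.origin, v.voxel_size))
        up = tuple(l + n * s for l, n, s in zip(lo, v.shape, v.voxel_size))
        return cls(lo, up, v.voxel_size)


@dataclasses.dataclass(frozen=True)
class PaxinosAxes:
    """Sign conventions of the Paxinos & Watson rat stereotaxic frame.

    x: negative left of the midline, positive right; y: positive ventral;
    z: positive toward the olfactory bulb, negative toward the cerebellum,
    reported relative to bregma (z_bregma_offset mm is added to the stored
    D3V-origin z when reporting).
    """

    signs: tuple[int, int, int] = (1, 1, 1)
    z_reference: str = "bregma"
    z_bregma_offset: float = 0.0


#: Template-space bounding box and voxel size of the normalization stage.
STANDARD_GRID = GridSpec(
    lower=(-150.0, -180.0, -126.0), upper=(150.0, 60.0, 72.0), voxel_size=(1.0, 1.0, 1.8)
)

#: Matrix the normalized intracranial image is sheared to, cutting background.
SHEAR_DIMS = (120, 80, 98)


# ---------------------------------------------------------------------------
# I/O


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".hdr", ".img", ".img.gz")):
        return "analyze"
    raise ValueError(f"cannot infer volume format from file name {path.name!r}")


def read_volume(path, format: str = "auto", space: str = "native") -> Volume:
    """Read an Analyze 7.5 or NIfTI-1 volume into a float :class:`Volume`.

    Intensities are promoted to float64 regardless of the on-disk type.
    For NIfTI the origin voxel is recovered from the sform/qform translation;
    Analyze lacks a portable origin field, so the grid centre is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    fmt = _detect_format(path) if format == "auto" else format
    if fmt not in ("analyze", "nifti"):
        raise ValueError(f"unknown format {format!r}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    if fmt == "nifti" and img.affine is not None:
        # origin voxel i0 satisfies affine @ (i0,1) = 0 on the translation part
        aff = img.affine
        try:
            origin = tuple(np.linalg.solve(aff[:3, :3], -aff[:3, 3]))
        except np.linalg.LinAlgError:
            origin = tuple((n - 1) / 2.0 for n in data.shape)
    else:
        origin = tuple((n - 1) / 2.0 for n in data.shape)
    return Volume(data, voxel_size=voxel_size, origin=origin, space=space)


def write_volume(v: Volume, path, format: str = "auto", dtype=np.float32) -> Path:
    """Write a Volume as NIfTI-1 (.nii/.nii.gz) or Analyze 7.5 (.hdr/.img)."""
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    data = np.ascontiguousarray(v.data, dtype=dtype)
    if fmt == "nifti":
        aff = np.diag(list(v.voxel_size) + [1.0])
        aff[:3, 3] = -np.asarray(v.origin) * np.asarray(v.voxel_size)
        img = nib.Nifti1Image(data, aff)
        img.header.set_zooms(v.voxel_size)
    elif fmt == "analyze":
        img = nib.AnalyzeImage(data, None)
        img.header.set_zooms(v.voxel_size)
    else:
        raise ValueError(f"unknown format {format!r}")
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Header and grid arithmetic


def scale_voxel_header(v: Volume, factor: float) -> Volume:
    """Multiply the header voxel size by ``factor``, leaving the data alone.

    Scaling a rodent header up by 4 makes the brain approximate human
    dimensions, which keeps human-calibrated registration defaults usable.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    return v.copy(voxel_size=tuple(s * factor for s in v.voxel_size))


def grid_dims(g: GridSpec) -> tuple[int, int, int]:
    """Voxel counts of a GridSpec under the half-open [lower, upper) rule."""
    lo = np.asarray(g.lower, float)
    up = np.asarray(g.upper, float)
    vs = np.asarray(g.voxel_size, float)
    dims = np.round((up - lo) / vs).astype(int)
    if np.any(dims <= 0):
        raise ValueError(f"degenerate grid dims {tuple(dims)}")
    return tuple(int(d) for d in dims)


def voxel_to_paxinos(v: Volume, idx, axes: PaxinosAxes = PaxinosAxes()) -> tuple[float, float, float]:
    """Map a voxel index to Paxinos mm coordinates (z reported versus bregma)."""
    idx = np.asarray(idx, float)
    if idx.shape != (3,):
        raise ValueError("idx must be a voxel index triple")
    if np.any(idx < 0) or np.any(idx > np.asarray(v.shape) - 1):
        raise IndexError(f"voxel index {tuple(idx)} outside grid {v.shape}")
    mm = (idx - np.asarray(v.origin)) * np.asarray(v.voxel_size) * np.asarray(axes.signs)
    mm[2] += axes.z_bregma_offset
    return tuple(float(c) for c in mm)


def paxinos_to_voxel(v: Volume, mm, axes: PaxinosAxes = PaxinosAxes()) -> tuple[float, float, float]:
    """Inverse of :func:`voxel_to_paxinos`; returns fractional voxel indices."""
    mm = np.asarray(mm, dtype=float).copy()
    mm[2] -= axes.z_bregma_offset
    idx = mm / (np.asarray(v.voxel_size) * np.asarray(axes.signs)) + np.asarray(v.origin)
    return tuple(float(c) for c in idx)


# ---------------------------------------------------------------------------
# Resampling


def _voxel_to_mm_matrix(v: Volume) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = np.diag(v.voxel_size)
    m[:3, 3] = -np.asarray(v.origin) * np.asarray(v.voxel_size)
    return m


def _grid_to_mm_matrix(g: GridSpec) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = np.diag(g.voxel_size)
    m[:3, 3] = np.asarray(g.lower)
    return m


def resample(src: Volume, onto: GridSpec, transform=None, interpolation: str = "trilinear") -> Volume:
    """Pull ``src`` onto the target grid through ``transform``.

    ``transform`` maps target mm coordinates into source mm coordinates
    (identity when None).  Out-of-field voxels are 0.  Use ``nearest`` for
    label/mask volumes and ``trilinear`` for intensities.
    """
    from .registration import Transform  # local import to avoid a cycle

    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "trilinear" else 0

    tgt2mm = _grid_to_mm_matrix(onto)
    dims = onto.dims
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij", sparse=False
    )
    vox = np.stack([ii, jj, kk], axis=0).reshape(3, -1).astype(float)
    mm = tgt2mm[:3, :3] @ vox + tgt2mm[:3, 3:4]

    if transform is not None:
        if not isinstance(transform, Transform):
            transform = Transform(affine=transform)
        mm = transform.map_mm(mm)

    mm2src = np.linalg.inv(_voxel_to_mm_matrix(src))
    src_vox = mm2src[:3, :3] @ mm + mm2src[:3, 3:4]

    from scipy.ndimage import map_coordinates

    out = map_coordinates(
        np.asarray(src.data, float), src_vox, order=order, mode="constant", cval=0.0
    ).reshape(dims)
    return Volume(out, voxel_size=onto.voxel_size, origin=onto.origin, space=src.space)
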