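"""Otsu-threshold intracranial extraction inside declared bounding boxes.

The intracranial tissue is isolated in three steps: zero everything outside
per-slice (or volumetric) rectangular brain boxes and inside optional eye
boxes, pool the remaining nonzero intensities, and keep voxels above the
single global threshold that maximizes Otsu's between-class variance.  The
boxes replace interactive two-click tracing with a plain-text sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .volume import Volume

__all__ = ["Box", "BoxSpec", "otsu_threshold", "extract_brain", "apply_mask", "default_box"]


@dataclasses.dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle: inclusive upper-left / lower-right voxel vertices.

    Boxes are drawn on coronal (fixed-z) slices, so vertices are (i, j)
    voxel pairs; ``slice_index`` of None means the box applies to every slice
    (volumetric box).
    """

    upper_left: tuple[int, int]
    lower_right: tuple[int, int]
    slice_index: int | None = None

    def __post_init__(self):
        ul, lr = self.upper_left, self.lower_right
        if lr[0] < ul[0] or lr[1] < ul[1]:
            raise ValueError(f"lower-right {lr} must be >= upper-left {ul} componentwise")

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        (i0, j0), (i1, j1) = self.upper_left, self.lower_right
        if i1 >= shape[0] or j1 >= shape[1]:
            raise ValueError(f"box {self} exceeds grid {shape}")
        m = np.zeros(shape, dtype=bool)
        if self.slice_index is None:
            m[i0 : i1 + 1, j0 : j1 + 1, :] = True
        else:
            if not 0 <= self.slice_index < shape[2]:
                raise ValueError(f"slice {self.slice_index} outside grid {shape}")
            m[i0 : i1 + 1, j0 : j1 + 1, self.slice_index] = True
        return m


@dataclasses.dataclass
class BoxSpec:
    """Brain boxes (keep inside) and eye boxes (drop inside)."""

    brain_boxes: list[Box]
    eye_boxes: list[Box] = dataclasses.field(default_factory=list)

    def brain_mask(self, shape) -> np.ndarray:
        if not self.brain_boxes:
            raise ValueError("BoxSpec has no brain boxes")
        keep = np.zeros(shape, dtype=bool)
        for b in self.brain_boxes:
            keep |= b.mask(shape)
        for b in self.eye_boxes:
            keep &= ~b.mask(shape)
        return keep

    # Sidecar format: one box per line,
    #   brain|eye  slice|*  i0 j0 i1 j1
    def write(self, path) -> Path:
        lines = ["# kind slice i0 j0 i1 j1"]
        for kind, boxes in (("brain", self.brain_boxes), ("eye", self.eye_boxes)):
            for b in boxes:
                sl = "*" if b.slice_index is None else str(b.slice_index)
                lines.append(
                    f"{kind} {sl} {b.upper_left[0]} {b.upper_left[1]} "
                    f"{b.lower_right[0]} {b.lower_right[1]}"
                )
        Path(path).write_text("\n".join(lines) + "\n")
        return Path(path)

    @classmethod
    def read(cls, path) -> "BoxSpec":
        brain, eyes = [], []
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            kind, sl, i0, j0, i1, j1 = line.split()
            box = Box(
                (int(i0), int(j0)),
                (int(i1), int(j1)),
                None if sl == "*" else int(sl),
            )
            (brain if kind == "brain" else eyes).append(box)
        return cls(brain, eyes)


def default_box(v: Volume, margin: int = 2) -> BoxSpec:
    """Generous volumetric brain box from the nonzero intensity support."""
    nz = np.nonzero(v.data != 0)
    if nz[0].size == 0:
        raise ValueError("volume has no nonzero voxels; cannot derive a default box")
    i0 = max(int(nz[0].min()) - margin, 0)
    i1 = min(int(nz[0].max()) + margin, v.shape[0] - 1)
    j0 = max(int(nz[1].min()) - margin, 0)
    j1 = min(int(nz[1].max()) + margin, v.shape[1] - 1)
    return BoxSpec([Box((i0, j0), (i1, j1), None)])


def otsu_threshold(values, bins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Returns the bin edge separating the two classes; with several
    equal-variance maximizers the lowest edge is returned (retains more
    tissue — the mask is refined by registration downstream).
    """
    values = np.asarray(values, float).ravel()
    if values.size < 2 or np.unique(values).size < 2:
        raise ValueError("Otsu threshold undefined for a (near-)constant sample")
    counts, edges = np.histogram(values, bins=bins)
    counts = counts.astype(float)
    total = counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])

    w0 = np.cumsum(counts)[:-1]  # class 0: bins 0..k inclusive, cut after bin k
    w1 = total - w0
    mu_cum = np.cumsum(counts * centers)[:-1]
    mu_total = (counts * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu_cum / w0
        m1 = (mu_total - mu_cum) / w1
        between = w0 * w1 * (m0 - m1) ** 2
    between[~np.isfinite(between)] = -np.inf
    # lowest cut among maximizers, with ties resolved at float tolerance
    # (an empty-bin gap between modes yields a plateau of equal variances)
    top = between.max()
    best = int(np.argmax(between >= top * (1.0 - 1e-12)))
    return float(edges[best + 1])


def extract_brain(v: Volume, boxes: BoxSpec | None = None, bins: int = 256):
    """Return (canonical brain, binary mask) from one global Otsu threshold.

    Voxels outside the brain boxes or inside eye boxes are zeroed; the
    threshold is computed from the remaining nonzero voxels of the whole
    volume at once, then the canonical brain keeps intensities strictly
    above it.
    """
    if boxes is None:
        boxes = default_box(v)
    keep = boxes.brain_mask(v.shape)
    boxed = np.where(keep, v.data, 0.0)
    sample = boxed[boxed != 0]
    if sample.size == 0:
        raise ValueError("boxes exclude every nonzero voxel; nothing to extract")
    thr = otsu_threshold(sample, bins=bins)
    mask = (boxed > thr).astype(np.float64)
    canonical = np.where(mask > 0, v.data, 0.0)
    return (
        v.copy(data=canonical),
        v.copy(data=mask),
    )


def apply_mask(v: Volume, mask: Volume) -> Volume:
    """Elementwise product with a mask on the same grid."""
    if v.shape != mask.shape:
        raise ValueError(f"grid mismatch: {v.shape} vs {mask.shape}")
    return v.copy(data=v.data * (mask.data != 0))
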