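"""Synthetic FDG-PET target construction from an integer-coded atlas.

A label atlas in stereotaxic space is reduced to six gross structures
(1 olfactory bulb, 2 cortex, 3 hippocampi, 4 mesencephalon, 5 thalamus,
6 cerebellum), each structure is painted with the mean intensity of the
corresponding region in a reference PET volume, and the piecewise-constant
image is Gaussian-smoothed to soften junctures.  The result is a PET-like
image in atlas space that an intensity-based registration can lock onto,
which is how the canonical PET brain is carried into Paxinos space.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import Volume

__all__ = [
    "STRUCTURE_NAMES",
    "merge_labels",
    "assign_region_means",
    "smooth_gaussian",
    "synthesize_pet",
    "read_label_mapping",
    "write_label_mapping",
]

#: Fixed structure ids of the merged six-structure atlas.
STRUCTURE_NAMES = {
    1: "olfactory bulb",
    2: "cortex",
    3: "hippocampi",
    4: "mesencephalon",
    5: "thalamus",
    6: "cerebellum",
}

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def merge_labels(atlas: Volume, mapping: dict[int, int | str]) -> Volume:
    """Collapse fine atlas labels into the six structures.

    ``mapping`` sends every nonzero atlas label to a structure id in 1..6 or
    to the string ``"drop"``; unmapped nonzero labels are an error so silent
    label loss cannot happen.
    """
    data = np.asarray(atlas.data)
    labels = np.unique(data)
    labels = labels[labels != 0]
    if np.any(labels != np.round(labels)):
        raise ValueError("atlas volume contains non-integer labels")
    missing = [int(l) for l in labels if int(l) not in mapping]
    if missing:
        raise KeyError(f"atlas labels without a mapping entry: {missing}")
    bad = {k: s for k, s in mapping.items() if s != "drop" and int(s) not in STRUCTURE_NAMES}
    if bad:
        raise ValueError(f"mapped structure ids outside 1..6: {bad}")

    out = np.zeros_like(data, dtype=np.int32)
    for lab in labels:
        s = mapping[int(lab)]
        if s != "drop":
            out[data == lab] = int(s)
    return atlas.copy(data=out)


def assign_region_means(labels: Volume, reference: Volume) -> Volume:
    """Paint each structure with the mean reference intensity over it."""
    if labels.shape != reference.shape:
        raise ValueError(f"grid mismatch: {labels.shape} vs {reference.shape}")
    lab = np.asarray(labels.data).astype(int)
    out = np.zeros(lab.shape, dtype=np.float64)
    for s in np.unique(lab):
        if s == 0:
            continue
        sel = lab == s
        if not sel.any():
            continue
        out[sel] = float(np.asarray(reference.data)[sel].mean())
    for s in STRUCTURE_NAMES:
        if not (lab == s).any():
            warnings.warn(f"structure {s} ({STRUCTURE_NAMES[s]}) has no voxels; assigned 0")
    return labels.copy(data=out)


def smooth_gaussian(v: Volume, fwhm) -> Volume:
    """Separable Gaussian smoothing with per-axis FWHM in mm.

    sigma_axis = FWHM_axis / (voxel_size_axis * sqrt(8 ln 2)).  Boundaries
    are zero-padded: background in masked PET genuinely is zero signal, at
    the price of shrunk intensities within ~1 FWHM of the field edge.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm, float), (3,))
    if np.any(fwhm < 0):
        raise ValueError(f"FWHM must be non-negative, got {tuple(fwhm)}")
    sigma_vox = fwhm * FWHM_TO_SIGMA / np.asarray(v.voxel_size)
    if np.all(sigma_vox == 0):
        return v.copy()
    out = ndimage.gaussian_filter(
        np.asarray(v.data, float), sigma=tuple(sigma_vox), mode="constant", cval=0.0
    )
    return v.copy(data=out)


def synthesize_pet(atlas: Volume, mapping, reference: Volume, fwhm=(2.0, 2.0, 4.0)) -> Volume:
    """Merged labels -> region means -> smoothing: the registration target."""
    merged = merge_labels(atlas, mapping)
    painted = assign_region_means(merged, reference)
    return smooth_gaussian(painted, fwhm)


# ---------------------------------------------------------------------------
# Two-column plain-text mapping table: "atlas_label structure_id|drop"


def read_label_mapping(path) -> dict[int, int | str]:
    mapping: dict[int, int | str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        lab, target = line.split()
        mapping[int(lab)] = "drop" if target == "drop" else int(target)
    return mapping


def write_label_mapping(mapping: dict[int, int | str], path) -> Path:
    lines = ["# atlas_label structure_id (1-6) or 'drop'"]
    for lab in sorted(mapping):
        lines.append(f"{lab} {mapping[lab]}")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)
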