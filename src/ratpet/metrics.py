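"""Volumetric and spatial correspondence measures for binary mask pairs.

Given a reference mask R and an evaluated mask S (voxel counts V(.)):

* Jaccard similarity      JS = 100 * V(R n S) / V(R u S)        (optimal 100%)
* relative volume error   RV = 100 * |V(S) - V(R)| / V(R)       (optimal 0%)
* false-positive fraction FP = 100 * V(S \\ R) / V(R u S)        (optimal 0%)
* false-negative fraction FN = 100 * V(R \\ S) / V(R u S)        (optimal 0%)

FP and FN share the union denominator, so JS + FP + FN = 100 holds exactly
for every mask pair — the identity that makes the three numbers a partition
of the union.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .volume import Volume

__all__ = ["OverlapReport", "overlap_report", "batch_overlap_table"]


@dataclasses.dataclass(frozen=True)
class OverlapReport:
    """The four percentages plus the raw voxel counts behind them."""

    js: float
    rv: float
    fp: float
    fn: float
    n_reference: int
    n_evaluated: int
    n_intersection: int
    n_union: int

    def as_dict(self) -> dict[str, float]:
        return {"JS": self.js, "RV": self.rv, "FP": self.fp, "FN": self.fn}


def _as_binary(v, name: str) -> np.ndarray:
    arr = v.data if isinstance(v, Volume) else np.asarray(v)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(
            f"{name} mask is not binary (values {vals[:8]}...); binarize explicitly first"
        )
    return arr.astype(bool)


def overlap_report(reference, evaluated) -> OverlapReport:
    """Compare two binary masks on one grid; raises on empty union."""
    r = _as_binary(reference, "reference")
    s = _as_binary(evaluated, "evaluated")
    if r.shape != s.shape:
        raise ValueError(f"grid mismatch: {r.shape} vs {s.shape}")
    n_r = int(r.sum())
    n_s = int(s.sum())
    n_i = int((r & s).sum())
    n_u = int((r | s).sum())
    if n_u == 0:
        raise ValueError("both masks are empty; overlap metrics undefined")
    if n_r == 0:
        raise ValueError("reference mask is empty; RV undefined")
    js = 100.0 * n_i / n_u
    rv = 100.0 * abs(n_s - n_r) / n_r
    fp = 100.0 * (n_s - n_i) / n_u
    fn = 100.0 * (n_r - n_i) / n_u
    return OverlapReport(js, rv, fp, fn, n_r, n_s, n_i, n_u)


def batch_overlap_table(pairs: dict[str, list[tuple]]) -> pd.DataFrame:
    """Mean +/- SD of the four measures across mask pairs, per named row.

    ``pairs`` maps a row label (e.g. one animal) to a list of
    (reference, evaluated) mask pairs; the layout mirrors the usual
    per-subject evaluation tables.
    """
    rows = {}
    for label, pair_list in pairs.items():
        reports = [overlap_report(r, s).as_dict() for r, s in pair_list]
        df = pd.DataFrame(reports)
        rows[label] = {
            metric: f"{df[metric].mean():.2f}±{df[metric].std(ddof=1):.2f}"
            if len(df) > 1
            else f"{df[metric].mean():.2f}"
            for metric in ("JS", "RV", "FP", "FN")
        }
    out = pd.DataFrame(rows).T
    out.columns = ["JS (%)", "RV (%)", "FP (%)", "FN (%)"]
    return out
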