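"""Sliding pseudotime windows and virtual-cell aggregation.

Cells of each cluster are grouped into overlapping windows that slide
along the shared pseudotime axis (interval 0.2 of the range, advancing
by 0.01), and each window's member cells are collapsed into a single
*virtual cell*: the per-gene shifted geometric mean of their depth-
normalized expression.  Across the full table the per-gene values are
divided by their median over every (cluster, window) column and log2
transformed, so a virtual cell reads as log fold change over the typical
window.

A raw geometric mean is zero as soon as one member has a zero count, so
the geometric mean is taken on 1 + expression and shifted back — the
stage-1 value of a gene whose members all express c is exactly c.
Windowing uses the global [0, 1] pseudotime range for every cluster, so
columns are directly comparable across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .preprocess import NormalizedMatrix
from .trajectory import PhaseBands, PseudotimeAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "make_windows",
    "window_members",
    "virtual_cell",
    "VirtualCellTable",
    "aggregate_virtual_cells",
    "assign_window_band",
]

_EPS = 1e-9


def make_windows(
    interval: float = 0.2, increment: float = 0.01
) -> list[tuple[float, float]]:
    """Window bounds [s, s + interval] for s = 0, increment, ..., 1 - interval.

    The last start position 1 - interval is included (tolerance 1e-9);
    defaults give 81 windows, the first [0, 0.2], the last [0.8, 1.0].
    """
    if not 0 < interval <= 1:
        raise ValueError("interval must be in (0, 1]")
    if not 0 < increment <= interval:
        raise ValueError("increment must be in (0, interval]")
    n = int(np.floor((1.0 - interval) / increment + _EPS)) + 1
    return [(round(i * increment, 12), round(i * increment + interval, 12)) for i in range(n)]


def window_members(
    pt: np.ndarray, start: float, end: float, is_last: bool
) -> np.ndarray:
    """Boolean membership mask: start <= pt < end, except that the final
    window also includes pt == 1."""
    pt = np.asarray(pt, dtype=float)
    mask = (pt >= start - _EPS) & (pt < end - _EPS)
    if is_last:
        mask |= pt >= end - _EPS  # close the right edge at pt = 1
    return mask


def virtual_cell(expr, members: np.ndarray | None = None) -> np.ndarray:
    """Stage-1 aggregation: per-gene shifted geometric mean over members.

    ``expr`` is cells x genes (sparse or dense) linear-scale expression;
    ``members`` is a boolean mask or index array (default: all rows).
    Returns ``exp(mean(ln(1 + expr))) - 1`` per gene, which equals the
    plain value for constant input and the single cell's expression for
    one member.
    """
    x = expr if members is None else expr[members]
    if sp.issparse(x):
        x = x.copy()
        x.data = np.log1p(x.data)
        mean_log = np.asarray(x.mean(axis=0)).ravel()
    else:
        mean_log = np.log1p(np.asarray(x, dtype=float)).mean(axis=0)
    return np.expm1(mean_log)


@dataclass
class VirtualCellTable:
    """Aggregated expression of every (cluster, window).

    ``profiles``: genes x columns DataFrame of the final log2 ratios;
    ``geomeans``: the stage-1 shifted geometric means on the same
    (full) gene universe; ``meta``: one row per column with the window
    bounds, midpoint and member count.  Columns are a MultiIndex
    (cluster, window index).
    """

    profiles: pd.DataFrame
    geomeans: pd.DataFrame
    meta: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return self.meta.shape[0]


def aggregate_virtual_cells(
    norm: NormalizedMatrix,
    clusters: pd.Series,
    pt: PseudotimeAssignment | pd.Series,
    interval: float = 0.2,
    increment: float = 0.01,
    min_members: int = 5,
) -> VirtualCellTable:
    """Build the full virtual-cell table over all clusters and windows.

    Windows below ``min_members`` cells are dropped (logged), not an
    error.  Stage 2 divides each gene by its median over *all* retained
    (cluster, window) columns pooled across clusters; genes whose median
    is zero are excluded from the final profiles (logged).  Stage 3 is
    ``log2(1 + ratio)``.
    """
    pts = pt.pt if isinstance(pt, PseudotimeAssignment) else pt
    clusters = clusters.reindex(norm.cell_ids)
    pts = pts.reindex(norm.cell_ids)
    expr = norm.linear()
    bounds = make_windows(interval, increment)

    cols, meta_rows = [], []
    n_dropped = 0
    for cl in sorted(clusters.dropna().unique()):
        in_cl = (clusters == cl).to_numpy()
        cl_pt = pts.to_numpy(dtype=float)
        for w, (s, e) in enumerate(bounds):
            mask = in_cl & window_members(cl_pt, s, e, is_last=(w == len(bounds) - 1))
            n = int(mask.sum())
            if n == 0:
                continue
            if n < min_members:
                n_dropped += 1
                continue
            cols.append(virtual_cell(expr, np.flatnonzero(mask)))
            meta_rows.append((cl, w, s, e, (s + e) / 2.0, n))
    if n_dropped:
        logger.info("dropped %d windows below min_members=%d", n_dropped, min_members)
    if not cols:
        raise ValueError("no window reached min_members cells")

    meta = pd.DataFrame(
        meta_rows, columns=["cluster", "window", "start", "end", "midpoint", "n_cells"]
    )
    col_index = pd.MultiIndex.from_frame(meta[["cluster", "window"]])
    geomeans = pd.DataFrame(
        np.column_stack(cols), index=norm.gene_symbols, columns=col_index
    )

    med = geomeans.median(axis=1)
    nonzero = med > 0
    if (~nonzero).any():
        logger.info(
            "%d genes with zero across-table median excluded from profiles",
            int((~nonzero).sum()),
        )
    ratios = geomeans.loc[nonzero].div(med[nonzero], axis=0)
    profiles = np.log2(1.0 + ratios)
    meta.index = col_index
    return VirtualCellTable(profiles=profiles, geomeans=geomeans, meta=meta)


def assign_window_band(midpoint: float, bands: PhaseBands) -> str:
    """Band (M / P / Q) of a window, judged by its midpoint under the cuts."""
    if midpoint >= bands.cut_q:
        return "Q"
    if midpoint < bands.cut_m:
        return "M"
    return "P"
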