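"""Linear pseudotime from cycle-gene expression, and the M / P / Q bands.

The trajectory is a one-dimensional principal curve fitted to cells in a
low-dimensional embedding of their cycle-gene profiles:

1. subset the expression matrix to the union of the cycle gene sets;
2. pairwise cell distance = 1 - Spearman rank correlation;
3. classical multidimensional scaling to ``n_dims`` components;
4. initial path through k-means centroids (k = 4), ordered by the
   shortest open Hamiltonian path over centroid distances;
5. principal-curve refinement: alternate projecting cells onto the
   current polyline and lowess-smoothing each embedding coordinate
   against arc-length, until the projections move less than ``tol`` or
   ``max_iter`` iterations;
6. pseudotime = arc-length position, min-max rescaled to [0, 1];
7. orientation: mitotic cells must sit at low pseudotime (the axis is
   flipped when cells rich in G2M/M expression land above cells rich in
   G0 expression).

Cells are processed in a canonical (sorted-by-id) order internally, so
the result is exactly invariant to the input cell order.

The phase *bands* collapse the six phases onto the axis: mitosis
(G2M + M), growth/proliferation (MG1 + G1S + S) and quiescence (G0).
Band cuts can be derived from the data by the bin-majority rule or fall
back to the fixed defaults 0.20 / 0.69.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import GeneSetCollection
from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PseudotimeAssignment",
    "PhaseBands",
    "infer_linear_pseudotime",
    "derive_bands",
]

#: The three phase super-groups on the linear axis.
BAND_GROUPS = {
    "M": ("G2M", "M"),
    "P": ("MG1", "G1S", "S"),
    "Q": ("G0",),
}


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime in [0, 1] plus fit metadata."""

    pt: pd.Series  # index: cell_id
    flipped: bool
    n_dims: int

    def __post_init__(self) -> None:
        v = self.pt.to_numpy()
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("pseudotime out of [0, 1]")


@dataclass
class PhaseBands:
    """Band per cell (M / P / Q) and the pseudotime cuts that define them."""

    band: pd.Series  # index: cell_id
    cut_m: float
    cut_q: float
    derived: bool  # True if the cuts came from the bin-majority rule


# ---------------------------------------------------------------------------
# pseudotime


def _classical_mds(d: np.ndarray, n_dims: int) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix to ``n_dims``."""
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    b = (b + b.T) / 2.0
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    lam = np.maximum(vals[order], 0.0)
    coords = vecs[:, order] * np.sqrt(lam)[None, :]
    # deterministic sign: the entry with the largest magnitude is positive
    for k in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] *= -1.0
    return coords


def _hamiltonian_order(centroids: np.ndarray) -> list[int]:
    """Exhaustive shortest open path through the centroids (k is small)."""
    k = len(centroids)
    dist = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    best, best_len = None, np.inf
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:  # a path equals its reverse
            continue
        length = sum(dist[a, b] for a, b in zip(perm, perm[1:]))
        if length < best_len:
            best, best_len = perm, length
    return list(best)


def _project_to_polyline(
    points: np.ndarray, curve: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal projection of each point onto a polyline.

    Returns (arc-length positions, projected coordinates).
    """
    seg = np.diff(curve, axis=0)  # (m-1, d)
    seg_len2 = np.maximum((seg**2).sum(axis=1), 1e-300)
    arc = np.concatenate([[0.0], np.cumsum(np.sqrt((seg**2).sum(axis=1)))])

    # t[i, j]: position of point i along segment j, clipped to [0, 1]
    diff = points[:, None, :] - curve[None, :-1, :]  # (n, m-1, d)
    t = np.clip((diff * seg[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = curve[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    jbest = np.argmin(d2, axis=1)
    n = len(points)
    tbest = t[np.arange(n), jbest]
    lam = arc[jbest] + tbest * np.sqrt(seg_len2[jbest])
    return lam, proj[np.arange(n), jbest]


def _smooth_curve(
    coords: np.ndarray, lam: np.ndarray, span: float, n_points: int = 100
) -> np.ndarray:
    """New curve: lowess of each coordinate against arc-length position."""
    order = np.argsort(lam, kind="stable")
    lam_s = lam[order]
    smoothed = np.empty_like(coords)
    # ties in lam (cells projected onto the same curve endpoint) trigger a
    # harmless 0/0 inside lowess; the smoothed values stay finite
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in range(coords.shape[1]):
            smoothed[order, k] = lowess(
                coords[order, k], lam_s, frac=span, it=0, return_sorted=False
            )
    # downsample along the sorted positions to a manageable polyline
    idx = np.unique(
        np.linspace(0, len(lam) - 1, min(n_points, len(lam))).astype(int)
    )
    return smoothed[order][idx]


def infer_linear_pseudotime(
    norm: NormalizedMatrix,
    cycle_sets: GeneSetCollection,
    n_dims: int = 3,
    k_centers: int = 4,
    span: float = 0.2,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
    mitosis_sets: tuple[str, ...] = ("G2M", "M"),
    quiescence_sets: tuple[str, ...] = ("G0",),
) -> PseudotimeAssignment:
    """Order cells along a linear trajectory using cycle-gene expression.

    Parameters follow the module docstring; ``mitosis_sets`` and
    ``quiescence_sets`` name which members of ``cycle_sets`` anchor the
    orientation (low and high pseudotime respectively).
    """
    if norm.n_cells < max(10, k_centers):
        raise ValueError("too few cells for trajectory inference")
    gene_idx = norm.gene_index(cycle_sets.union())
    if len(gene_idx) < 2:
        raise ValueError("cycle-set genes not found in the matrix")

    # canonical cell order => exact permutation invariance
    cell_order = np.argsort(norm.cell_ids.astype(str), kind="stable")
    x = np.asarray(norm.values[cell_order][:, gene_idx].todense(), dtype=float)

    ranks = rankdata(x, axis=1)
    if np.any(ranks.std(axis=1) == 0):
        raise ValueError("cells with constant cycle-gene expression")
    corr = np.corrcoef(ranks)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    if np.allclose(d, 0.0):
        raise ValueError("zero distance matrix: expression is constant")

    coords = _classical_mds(d, n_dims)

    km = KMeans(n_clusters=k_centers, random_state=seed % (2**31), n_init=10)
    km.fit(coords)
    path = _hamiltonian_order(km.cluster_centers_)
    curve = km.cluster_centers_[path]
    # densify the initial polyline
    lam0, _ = _project_to_polyline(coords, curve)
    curve = _smooth_curve(coords, lam0, span)

    prev_proj = None
    scale = np.sqrt((coords.var(axis=0)).sum())  # for the convergence scale
    for it in range(max_iter):
        lam, proj = _project_to_polyline(coords, curve)
        if prev_proj is not None:
            shift = np.sqrt(((proj - prev_proj) ** 2).sum(axis=1)).mean()
            if shift < tol * max(scale, 1e-300):
                break
        prev_proj = proj
        curve = _smooth_curve(coords, lam, span)
    lam, _ = _project_to_polyline(coords, curve)

    span_lam = lam.max() - lam.min()
    if span_lam <= 0:
        raise ValueError("degenerate principal curve (zero length)")
    pt = (lam - lam.min()) / span_lam

    # orientation: mitotic expression low on the axis, quiescent high
    flipped = False
    mito = [s for s in mitosis_sets if s in cycle_sets.names]
    quies = [s for s in quiescence_sets if s in cycle_sets.names]
    if mito and quies:
        mito_expr = x[:, _local_index(norm, gene_idx, cycle_sets, mito)].mean(axis=1)
        g0_expr = x[:, _local_index(norm, gene_idx, cycle_sets, quies)].mean(axis=1)
        m_pt = pt[mito_expr >= np.quantile(mito_expr, 0.9)].mean()
        q_pt = pt[g0_expr >= np.quantile(g0_expr, 0.9)].mean()
        if m_pt > q_pt:
            pt = 1.0 - pt
            flipped = True
    else:
        warnings.warn(
            "orientation anchors not found among cycle sets; axis direction "
            "is arbitrary",
            stacklevel=2,
        )

    series = pd.Series(np.empty(norm.n_cells), index=norm.cell_ids, name="pt")
    series.iloc[cell_order] = pt
    return PseudotimeAssignment(series, flipped=flipped, n_dims=n_dims)


def _local_index(
    norm: NormalizedMatrix,
    gene_idx: np.ndarray,
    cycle_sets: GeneSetCollection,
    set_names: list[str],
) -> np.ndarray:
    """Positions, within the cycle-gene submatrix, of the named sets' genes."""
    pos = {g: i for i, g in enumerate(gene_idx)}
    symbols = set()
    for s in set_names:
        symbols.update(cycle_sets[s])
    cols = [pos[i] for i in norm.gene_index(sorted(symbols)) if i in pos]
    return np.asarray(sorted(set(cols)), dtype=int)


# ---------------------------------------------------------------------------
# phase bands


def _bin_majorities(
    pt: np.ndarray, phases: np.ndarray, bin_width: float
) -> list[tuple[int, str]]:
    """(bin index, label) for each non-empty bin; label is the super-group
    holding a strict majority (> 50%) of the bin's cells, else 'mixed'."""
    n_bins = int(round(1.0 / bin_width))
    idx = np.clip((pt / bin_width).astype(int), 0, n_bins - 1)
    group_of = {p: g for g, ps in BAND_GROUPS.items() for p in ps}
    out = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        counts = pd.Series([group_of.get(p, "other") for p in phases[mask]])
        frac = counts.value_counts(normalize=True)
        label = "mixed"
        if frac.iloc[0] > 0.5 and frac.index[0] in BAND_GROUPS:
            label = str(frac.index[0])
        out.append((b, label))
    return out


def derive_bands(
    pt: PseudotimeAssignment | pd.Series,
    phases: pd.Series,
    bin_width: float = 0.05,
    cut_m_default: float = 0.20,
    cut_q_default: float = 0.69,
) -> PhaseBands:
    """Derive the M / P / Q cuts from bin majorities along pseudotime.

    Pseudotime is cut into fixed-width bins; each non-empty bin is
    labelled by the phase super-group holding more than 50% of its cells.
    A clean changepoint structure (mitosis bins, then growth bins, then
    quiescence bins, with mixed bins only at the seams) yields data-
    derived cuts at the seams; otherwise the fixed default cuts are used
    with a warning.  Band membership: M = pt < cut_m,
    P = cut_m <= pt < cut_q, Q = pt >= cut_q.
    """
    pts = pt.pt if isinstance(pt, PseudotimeAssignment) else pt
    phases = phases.reindex(pts.index)
    v = pts.to_numpy(dtype=float)
    labels = _bin_majorities(v, phases.to_numpy(dtype=object), bin_width)

    seq = [(b, lab) for b, lab in labels if lab != "mixed"]
    order = [lab for _, lab in seq]
    compressed = [k for k, _ in itertools.groupby(order)]
    clean = (
        compressed in (["M", "P", "Q"], ["P", "Q"])
        and "P" in order
        and "Q" in order
    )
    if clean:
        def edge(lo_bin: int, hi_bin: int) -> float:
            return ((lo_bin + 1) * bin_width + hi_bin * bin_width) / 2.0

        first_p = min(b for b, lab in seq if lab == "P")
        first_q = min(b for b, lab in seq if lab == "Q")
        last_p = max(b for b, lab in seq if lab == "P" and b < first_q)
        if "M" in order:
            last_m = max(b for b, lab in seq if lab == "M" and b < first_p)
            cut_m = edge(last_m, first_p)
        else:
            cut_m = 0.0
        cut_q = edge(last_p, first_q)
        derived = True
    else:
        warnings.warn(
            "no clean mitosis->growth->quiescence changepoints in the bin "
            f"majorities; falling back to cuts {cut_m_default}/{cut_q_default}",
            stacklevel=2,
        )
        cut_m, cut_q, derived = cut_m_default, cut_q_default, False

    band = np.full(len(v), "P", dtype=object)
    band[v < cut_m] = "M"
    band[v >= cut_q] = "Q"
    return PhaseBands(
        pd.Series(band, index=pts.index, name="band"),
        cut_m=float(cut_m),
        cut_q=float(cut_q),
        derived=derived,
    )
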