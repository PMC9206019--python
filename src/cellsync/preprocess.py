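"""Quality control, normalization and graph-based clustering of cells.

The QC rules are the usual droplet scRNA-seq ones: drop cells by detected
gene count and mitochondrial fraction, then drop genes seen in too few of
the surviving cells.  Cell metrics are always computed on the *original*
gene universe, so the cell filter does not depend on the gene filter.
Boundary cells (exactly 200 or 3700 detected genes, exactly 10%
mitochondrial) are kept: removal requires strictly "fewer than" /
"more than" the threshold.

Normalization is depth normalization to a fixed scale factor followed by
log1p.  Clustering selects dispersion-ranked variable genes, standardizes
them (clipped at +/-10), reduces with PCA, builds a k-nearest-neighbour
graph and partitions it with multilevel Louvain at a configurable
resolution.  Cluster labels are letters assigned by decreasing size
(A = largest), with size ties broken by the smallest contained cell index.
"""

from __future__ import annotations

import logging
import random
import string
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ClusterAssignment",
    "QCReport",
    "EmptyAfterQCError",
    "qc_filter",
    "log_normalize",
    "scale_genes",
    "cluster_cells",
]


class EmptyAfterQCError(ValueError):
    """Every cell was removed by the QC filters."""


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_low_genes: int
    n_cells_high_genes: int
    n_cells_high_mito: int
    n_genes_low_cells: int
    n_cells_out: int
    n_genes_out: int


@dataclass
class NormalizedMatrix:
    """Log-normalized expression, cells x genes, sparse.

    ``values[i, j] = ln(1 + count[i, j] / total_i * scale_factor)``; zero
    counts stay exactly zero.  The per-gene standardized ("scaled")
    variant is computed on demand via :func:`scale_genes`.
    """

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    gene_symbols: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        """Column indices of the given symbols (exact, case-sensitive);
        symbols absent from the matrix are silently skipped."""
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        return np.array([lookup[s] for s in symbols if s in lookup], dtype=int)

    def linear(self) -> sp.csr_matrix:
        """Depth-normalized expression on the linear scale (expm1 of values)."""
        out = self.values.copy()
        out.data = np.expm1(out.data)
        return out


@dataclass
class ClusterAssignment:
    """Per-cell cluster letters plus the parameters that produced them."""

    labels: pd.Series  # index: cell_id, values: "A", "B", ...
    params: dict = field(default_factory=dict)

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


def qc_filter(
    counts: CountMatrix,
    min_cells_per_gene: int = 3,
    min_genes: int = 200,
    max_genes: int = 3700,
    max_mito_frac: float = 0.10,
    mito_prefix: str = "MT-",
    return_report: bool = False,
) -> CountMatrix | tuple[CountMatrix, QCReport]:
    """Apply the cell and gene quality filters.

    Cells are removed if fewer than ``min_genes`` or more than
    ``max_genes`` genes are detected, or if mitochondrial genes (symbol
    prefix ``mito_prefix``) make up more than ``max_mito_frac`` of their
    counts — all computed on the full input gene universe.  Genes
    expressed in fewer than ``min_cells_per_gene`` surviving cells are
    then removed.
    """
    v = counts.values
    detected = np.asarray((v > 0).sum(axis=1)).ravel()
    total = np.asarray(v.sum(axis=1)).ravel().astype(float)
    is_mito = np.array(
        [str(s).startswith(mito_prefix) for s in counts.gene_symbols], dtype=bool
    )
    mito_counts = (
        np.asarray(v[:, is_mito].sum(axis=1)).ravel().astype(float)
        if is_mito.any()
        else np.zeros(counts.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_counts / np.maximum(total, 1e-300), 0.0)

    low = detected < min_genes
    high = detected > max_genes
    mito_bad = mito_frac > max_mito_frac
    keep_cells = ~(low | high | mito_bad)
    if not keep_cells.any():
        raise EmptyAfterQCError("no cells survive the QC filters")

    sub = counts.subset(cells=keep_cells)
    cells_per_gene = np.asarray((sub.values > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    out = sub.subset(genes=keep_genes)

    report = QCReport(
        n_cells_in=counts.n_cells,
        n_genes_in=counts.n_genes,
        n_cells_low_genes=int(low.sum()),
        n_cells_high_genes=int(high.sum()),
        n_cells_high_mito=int((mito_bad & ~low & ~high).sum()),
        n_genes_low_cells=int((~keep_genes).sum()),
        n_cells_out=out.n_cells,
        n_genes_out=out.n_genes,
    )
    logger.info("QC: %s", report)
    if return_report:
        return out, report
    return out


def log_normalize(counts: CountMatrix, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Depth-normalize each cell to ``scale_factor`` counts and log1p."""
    total = np.asarray(counts.values.sum(axis=1)).ravel().astype(float)
    if (total == 0).any():
        raise ValueError("cells with zero total counts cannot be normalized")
    x = counts.values.astype(float).tocsr(copy=True)
    # scale each row by scale_factor / total, then log1p on stored entries
    scale = scale_factor / total
    x = sp.diags(scale) @ x
    x = sp.csr_matrix(x)
    x.data = np.log1p(x.data)
    return NormalizedMatrix(
        x, counts.cell_ids.copy(), counts.gene_ids.copy(), counts.gene_symbols.copy()
    )


def scale_genes(
    norm: NormalizedMatrix, gene_idx: np.ndarray | None = None, clip: float = 10.0
) -> np.ndarray:
    """Per-gene standardization over cells, clipped at ``+/-clip``.

    Returns a dense array; genes with zero variance become all-zero
    columns.  Means are computed over all retained cells, so the scaled
    matrix has per-gene mean 0 (before clipping).
    """
    x = norm.values if gene_idx is None else norm.values[:, gene_idx]
    x = np.asarray(x.todense(), dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # zero-variance genes -> 0 after centering
    return np.clip((x - mu) / sd, -clip, clip)


def _variable_gene_idx(norm: NormalizedMatrix, n_top: int, n_bins: int = 20) -> np.ndarray:
    """Dispersion-based variable-gene ranking (mean-binned z-scores).

    Mean and variance are taken on the linear (expm1) scale; the
    dispersion var/mean is z-scored within equal-frequency bins of the
    mean so that highly expressed genes do not dominate.
    """
    x = norm.linear()
    n = x.shape[0]
    mean = np.asarray(x.mean(axis=0)).ravel()
    sq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0) * n / max(n - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    expressed = mean > 0
    if expressed.sum() == 0:
        return np.array([], dtype=int)
    order = pd.Series(mean[expressed]).rank(method="first")
    bins = pd.qcut(order, q=min(n_bins, expressed.sum()), labels=False, duplicates="drop")
    z = np.zeros(norm.n_genes)
    d = np.log1p(disp[expressed])
    df = pd.DataFrame({"bin": bins.to_numpy(), "d": d})
    grp = df.groupby("bin")["d"]
    mu_b = grp.transform("mean").to_numpy()
    sd_b = grp.transform("std").fillna(0.0).to_numpy()
    zz = np.where(sd_b > 0, (d - mu_b) / np.where(sd_b > 0, sd_b, 1.0), 0.0)
    z[np.flatnonzero(expressed)] = zz
    n_top = min(n_top, int(expressed.sum()))
    idx = np.argsort(-z, kind="stable")[:n_top]
    return np.sort(idx)


def _letters() -> list[str]:
    base = list(string.ascii_uppercase)
    return base + [a + b for a in base for b in base]


def cluster_cells(
    norm: NormalizedMatrix,
    n_var_genes: int = 2000,
    n_pcs: int = 50,
    k_neighbors: int = 20,
    resolution: float = 0.2,
    seed: int = 0,
) -> ClusterAssignment:
    """Variable genes -> scaled PCA -> kNN graph -> Louvain communities.

    Deterministic under a fixed seed.  Labels are letters by decreasing
    cluster size; ties broken by the smallest contained cell index.
    Cells are processed in a canonical (sorted-by-id) order internally,
    so relabeling the input rows permutes the output consistently.
    """
    if norm.n_cells < k_neighbors + 1:
        raise ValueError(
            f"need at least k_neighbors+1 = {k_neighbors + 1} cells, "
            f"got {norm.n_cells}"
        )
    cell_order = np.argsort(norm.cell_ids.astype(str), kind="stable")
    norm = NormalizedMatrix(
        norm.values[cell_order],
        norm.cell_ids[cell_order],
        norm.gene_ids,
        norm.gene_symbols,
    )
    inverse = np.empty_like(cell_order)
    inverse[cell_order] = np.arange(len(cell_order))

    var_idx = _variable_gene_idx(norm, n_var_genes)
    if len(var_idx) == 0:  # fully degenerate input: everything identical
        labels = pd.Series(
            ["A"] * norm.n_cells, index=norm.cell_ids, name="cluster"
        ).iloc[inverse]
        return ClusterAssignment(labels, {"degenerate": True})
    x = scale_genes(norm, var_idx, clip=10.0)
    n_comp = int(min(n_pcs, x.shape[1], norm.n_cells - 1))
    if np.allclose(x, 0.0):
        emb = np.zeros((norm.n_cells, 1))
    else:
        solver = "full" if norm.n_cells <= 3000 else "randomized"
        pca = PCA(n_components=n_comp, svd_solver=solver, random_state=seed)
        emb = pca.fit_transform(x)

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(emb)
    _, nbr = nn.kneighbors(emb)
    edges = set()
    for i in range(norm.n_cells):
        for j in nbr[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=norm.n_cells, edges=sorted(edges))

    state = random.getstate()
    try:
        random.seed(seed)
        comm = g.community_multilevel(resolution=resolution)
    finally:
        random.setstate(state)
    membership = np.asarray(comm.membership)

    # canonical letter labels: by decreasing size, tie on smallest index
    info = []
    for c in np.unique(membership):
        members = np.flatnonzero(membership == c)
        info.append((-len(members), members.min(), c))
    letters = _letters()
    relabel = {c: letters[rank] for rank, (_, _, c) in enumerate(sorted(info))}
    labels = pd.Series(
        [relabel[c] for c in membership], index=norm.cell_ids, name="cluster"
    ).iloc[inverse]  # back to the caller's cell order
    params = {
        "n_var_genes": len(var_idx),
        "n_pcs": n_comp,
        "k_neighbors": k_neighbors,
        "resolution": resolution,
        "seed": seed,
    }
    return ClusterAssignment(labels, params)
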