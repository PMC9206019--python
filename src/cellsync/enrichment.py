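"""Single-sample GSEA of virtual-cell profiles, and 0-1 rescaling.

The enrichment score (ES) of a gene set in one expression profile is a
rank-based running sum: genes are ordered by decreasing expression, the
walk accumulates the weighted fraction of set genes encountered minus
the fraction of non-set genes encountered, and the ES is the sum of that
difference over every position.  Weights are |rank|^alpha with the
rank-from-the-bottom convention (the top gene weighs N, the bottom gene
1); alpha = 0.75 by default, and alpha = 0 reduces the score to a purely
rank-count statistic invariant to any strictly monotone transform of the
profile.  Ties in profile values are broken by gene identifier so the
walk is deterministic everywhere.

Scores are compared across (cluster, window) columns after per-gene-set
min-max scaling to [0, 1] over the entire table, so 0 and 1 are the
weakest and strongest enrichment of that set anywhere on the pseudotime
axis, in any cluster.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .windows import VirtualCellTable

__all__ = ["ssgsea", "score_collection", "scale_scores"]


def ssgsea(
    profile: pd.Series,
    gene_set: Iterable[str],
    alpha: float = 0.75,
    weight_mode: Literal["rank", "value"] = "rank",
) -> float:
    """Enrichment score of one gene set in one expression profile.

    Parameters
    ----------
    profile
        Expression values indexed by gene symbol (the gene universe).
    gene_set
        Gene symbols; members absent from the profile are dropped.
    alpha
        Weight exponent; 0 ignores magnitudes entirely.
    weight_mode
        "rank" weighs position i by ``N - i + 1`` (rank-normalized
        profile); "value" weighs by ``|profile value|``.

    Raises
    ------
    ValueError
        If the set covers none, or all, of the profile's genes, or the
        profile has fewer than two genes.
    """
    values = profile.to_numpy(dtype=float)
    genes = profile.index.to_numpy(dtype=object)
    n = len(values)
    if n < 2:
        raise ValueError("profile must cover at least 2 genes")
    members = set(gene_set) & set(genes)
    mask = np.array([g in members for g in genes], dtype=bool)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("gene set shares no genes with the profile")
    if m == n:
        raise ValueError("gene set covers the whole profile")

    # descending by value, ties by gene id (stable and platform-independent)
    order = np.lexsort((genes.astype(str), -values))
    sorted_mask = mask[order]
    if weight_mode == "rank":
        w = np.arange(n, 0, -1, dtype=float)  # N, N-1, ..., 1
    elif weight_mode == "value":
        w = np.abs(values[order])
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    wa = np.abs(w) ** alpha

    in_w = np.where(sorted_mask, wa, 0.0)
    denom = in_w.sum()
    if denom == 0:
        raise ValueError("all set genes have zero weight")
    p_in = np.cumsum(in_w) / denom
    p_out = np.cumsum(~sorted_mask) / float(n - m)
    return float(np.sum(p_in - p_out))


def score_collection(
    vtable: VirtualCellTable,
    collection: GeneSetCollection,
    alpha: float = 0.75,
    weight_mode: Literal["rank", "value"] = "rank",
) -> pd.DataFrame:
    """ssGSEA of every gene set against every virtual cell.

    Returns a long DataFrame with columns ``gene_set``, ``cluster``,
    ``window``, ``midpoint`` and ``es``.  Collection genes absent from
    the profiles are dropped per set; a set with no gene in the profiles
    is skipped with a warning (via :meth:`GeneSetCollection.subset_to`).
    """
    profiles = vtable.profiles
    usable = collection.subset_to(list(profiles.index))
    rows = []
    for col in profiles.columns:
        prof = profiles[col]
        cluster, window = col
        midpoint = vtable.meta.loc[col, "midpoint"]
        for name in usable.names:
            es = ssgsea(prof, usable[name], alpha=alpha, weight_mode=weight_mode)
            rows.append((name, cluster, window, midpoint, es))
    return pd.DataFrame(
        rows, columns=["gene_set", "cluster", "window", "midpoint", "es"]
    )


def scale_scores(es: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale ES to [0, 1] per gene set over all (cluster, window).

    Adds a ``scaled_es`` column.  A gene set whose scores are constant
    across the whole table is set to 0.5 everywhere, with a warning.
    """
    out = es.copy()
    scaled = pd.Series(np.nan, index=out.index, dtype=float)
    for name, grp in out.groupby("gene_set"):
        v = grp["es"].to_numpy(dtype=float)
        lo, hi = v.min(), v.max()
        if hi > lo:
            scaled.loc[grp.index] = (v - lo) / (hi - lo)
        else:
            warnings.warn(
                f"gene set {name!r} has constant ES; scaled to 0.5", stacklevel=2
            )
            scaled.loc[grp.index] = 0.5
    out["scaled_es"] = scaled
    return out
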