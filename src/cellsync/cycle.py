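"""Cell-cycle phase scoring against an arbitrary number of gene sets.

Each cell gets one module score per cycle gene set: the mean log-
normalized expression of the set's genes minus the mean expression of
expression-bin-matched control genes.  Control genes are drawn per set
gene, with replacement, from the gene's equal-frequency mean-expression
bin — which makes the score a contrast against genes of comparable
abundance rather than against the whole transcriptome.  A cell's phase
is the argmax over the set scores; exact ties resolve to the earlier
phase in the canonical order G2M, M, MG1, G1S, S, G0.  Every cell is
assigned a phase, even when all of its scores are negative.
"""

from __future__ import annotations

import zlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneSetCollection
from .preprocess import NormalizedMatrix
from .simulate import PHASE_ORDER

__all__ = [
    "module_score",
    "score_gene_sets",
    "assign_phase",
    "phase_fractions",
    "format_percent",
]


def _column_means(values, idx: np.ndarray) -> np.ndarray:
    return np.asarray(values[:, idx].mean(axis=1)).ravel()


def module_score(
    norm: NormalizedMatrix,
    genes: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    name: str = "",
) -> np.ndarray:
    """Bin-matched control score of one gene set, one value per cell.

    Genes are ranked by mean expression across cells and cut into
    ``n_bins`` equal-frequency bins; for every set gene, ``n_ctrl``
    control genes are drawn (with replacement, seeded from ``seed`` and
    the set name) from the non-set genes of its bin.  The score is
    mean(set genes) - mean(control draws).  Set genes absent from the matrix are ignored;
    a set with no genes in the matrix raises ``KeyError``.
    """
    if norm.n_genes < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} genes in the matrix")
    set_idx = norm.gene_index(genes)
    if len(set_idx) == 0:
        raise KeyError(f"gene set {name or '<unnamed>'!r}: no genes found in matrix")

    gene_means = np.asarray(norm.values.mean(axis=0)).ravel()
    order = np.argsort(gene_means, kind="stable")
    bin_of = np.empty(norm.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    rng = np.random.default_rng([seed % (2**31), zlib.crc32(name.encode())])
    in_set = np.zeros(norm.n_genes, dtype=bool)
    in_set[set_idx] = True
    ctrl_idx = []
    bins = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    for gi in set_idx:
        pool = bins[bin_of[gi]]
        # controls exclude the scored set itself, unless a bin holds
        # nothing else (then the full bin is the only available pool)
        outside = pool[~in_set[pool]]
        ctrl_idx.append(rng.choice(outside if len(outside) else pool,
                                   size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_idx)

    return _column_means(norm.values, set_idx) - _column_means(norm.values, ctrl_idx)


def score_gene_sets(
    norm: NormalizedMatrix,
    collection: GeneSetCollection,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every set in ``collection``; returns cells x sets DataFrame.

    Columns follow the canonical phase order when the collection is a
    six-phase cycle collection, otherwise the collection's own order.
    """
    names = [p for p in PHASE_ORDER if p in collection.names]
    names += [n for n in collection.names if n not in names]
    scores = {
        n: module_score(norm, collection[n], n_bins, n_ctrl, seed, name=n)
        for n in names
    }
    return pd.DataFrame(scores, index=norm.cell_ids)


def assign_phase(scores: pd.DataFrame) -> pd.Series:
    """Argmax phase per cell; ties go to the earlier column.

    Columns are reordered to the canonical phase order first when all of
    them are phase names, so the tie-break is G2M, M, MG1, G1S, S, G0.
    """
    if set(scores.columns) <= set(PHASE_ORDER):
        cols = [p for p in PHASE_ORDER if p in scores.columns]
        scores = scores[cols]
    if scores.isna().any().any():
        raise ValueError("missing values in score table")
    idx = np.argmax(scores.to_numpy(), axis=1)  # first max wins
    return pd.Series(
        scores.columns.to_numpy(dtype=object)[idx], index=scores.index, name="phase"
    )


def phase_fractions(
    phases: pd.Series,
    groups: pd.Series,
    collapse: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-group phase composition; rows (groups) sum to 1.

    ``collapse`` optionally maps phase -> coarser band label (e.g. the
    three-band view mitosis / growth / G0) before tabulating.
    """
    phases = phases.copy()
    if collapse is not None:
        phases = phases.map(lambda p: collapse.get(p, p))
    tab = pd.crosstab(groups, phases)
    return tab.div(tab.sum(axis=1), axis=0)


def format_percent(fraction: float) -> str:
    """Render a fraction the way the headline numbers are printed.

    Percentages are truncated (not rounded) at the displayed precision:
    one decimal below 10%, integer above.  230/7814 -> "2.9%",
    133/230 -> "57%".
    """
    pct = fraction * 100.0
    if pct < 10.0:
        return f"{np.floor(pct * 10 + 1e-9) / 10:.1f}%"
    return f"{int(np.floor(pct + 1e-9))}%"
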