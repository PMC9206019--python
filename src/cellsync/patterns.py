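"""Per-phase enrichment medians and P-like / Q-like / anti-P classification.

After virtual synchronization, each cluster's functional state is
summarized by the median scaled enrichment score of every gene set over
its proliferative (P) and quiescent (Q) windows.  In this summary the P
phase absorbs the short mitosis band, matching the two-phase P / Q
vocabulary (P: pt < 0.69, Q: pt >= 0.69).

Each non-reference (cluster, phase) activity vector over gene sets is
then correlated with the reference cluster's P and Q vectors and
labelled:

* ``P-like``  — more similar to reference-P, correlation >= threshold;
* ``Q-like``  — more similar to reference-Q, correlation >= threshold;
* ``anti-P``  — strongly anti-correlated with reference-P;
* ``unclassified`` otherwise.

The reference cluster's own P phase is always P-like with correlation
exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import PhaseBands
from .windows import VirtualCellTable, assign_window_band

__all__ = ["PhasePatternSummary", "phase_medians", "pattern_classify"]


@dataclass
class PhasePatternSummary:
    """Medians, correlations and pattern labels of the P / Q summary.

    ``medians``: gene sets x (cluster, phase) median scaled ES;
    ``grand_median``: per (cluster, phase) median across gene sets;
    ``correlations`` and ``labels`` are filled by
    :func:`pattern_classify`.
    """

    medians: pd.DataFrame
    grand_median: pd.Series
    reference: str | None = None
    r_threshold: float | None = None
    correlations: pd.DataFrame | None = None
    labels: pd.DataFrame | None = None


def phase_medians(
    scaled_es: pd.DataFrame,
    bands: PhaseBands,
    fold_m_into_p: bool = True,
) -> PhasePatternSummary:
    """Median scaled ES per (gene set, cluster, phase in {P, Q}).

    ``scaled_es`` is the long table from
    :func:`cellsync.enrichment.scale_scores`; each window's phase is its
    midpoint's band under ``bands`` (M-band windows fold into P by
    default).  A cluster with no windows in one phase simply lacks that
    column.
    """
    df = scaled_es.copy()
    band = df["midpoint"].map(lambda m: assign_window_band(float(m), bands))
    if fold_m_into_p:
        band = band.replace({"M": "P"})
    df["phase"] = band
    df = df[df["phase"].isin(["P", "Q"])]

    medians = df.pivot_table(
        index="gene_set", columns=["cluster", "phase"], values="scaled_es",
        aggfunc="median",
    )
    grand = medians.median(axis=0)
    grand.name = "grand_median"
    return PhasePatternSummary(medians=medians, grand_median=grand)


def pattern_classify(
    summary: PhasePatternSummary,
    reference: str = "A",
    r_threshold: float = 0.3,
    method: str = "pearson",
) -> PhasePatternSummary:
    """Correlate every (cluster, phase) vector with the reference P / Q
    vectors and attach pattern labels; also fills the full correlation
    matrix over all (cluster, phase) columns.

    Requires at least 3 gene sets (correlations of shorter vectors are
    degenerate) and both reference phases to be present.
    """
    med = summary.medians
    if med.shape[0] < 3:
        raise ValueError("need at least 3 gene sets to correlate")
    for phase in ("P", "Q"):
        if (reference, phase) not in med.columns:
            raise ValueError(f"reference cluster {reference!r} lacks phase {phase}")

    corr = med.corr(method=method)
    ref_p = corr[(reference, "P")]
    ref_q = corr[(reference, "Q")]

    rows = []
    for col in med.columns:
        cp, cq = float(ref_p[col]), float(ref_q[col])
        if cp >= cq and cp >= r_threshold:
            label = "P-like"
        elif cq > cp and cq >= r_threshold:
            label = "Q-like"
        elif cp <= -r_threshold:
            label = "anti-P"
        else:
            label = "unclassified"
        rows.append((col[0], col[1], cp, cq, label))
    labels = pd.DataFrame(
        rows, columns=["cluster", "phase", "corr_ref_p", "corr_ref_q", "label"]
    )
    return PhasePatternSummary(
        medians=med,
        grand_median=summary.grand_median,
        reference=reference,
        r_threshold=r_threshold,
        correlations=corr,
        labels=labels,
    )
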