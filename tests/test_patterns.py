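"""P/Q medians and correlation-pattern classification."""

import numpy as np
import pandas as pd
import pytest

from cellsync.patterns import PhasePatternSummary, pattern_classify, phase_medians
from cellsync.trajectory import PhaseBands


def _bands(cut_m=0.2, cut_q=0.69):
    return PhaseBands(pd.Series(dtype=object), cut_m, cut_q, derived=False)


def _es_table(entries):
    """entries: (gene_set, cluster, midpoint, scaled_es)."""
    rows = [(g, c, i, m, np.nan, s) for i, (g, c, m, s) in enumerate(entries)]
    return pd.DataFrame(
        rows, columns=["gene_set", "cluster", "window", "midpoint", "es", "scaled_es"]
    )


def test_constant_p_windows_median():
    entries = [("s1", "A", m, 0.3) for m in (0.3, 0.4, 0.5)]
    entries += [("s1", "A", m, 0.8) for m in (0.7, 0.8, 0.9)]
    summary = phase_medians(_es_table(entries), _bands())
    assert summary.medians.loc["s1", ("A", "P")] == pytest.approx(0.3)
    assert summary.medians.loc["s1", ("A", "Q")] == pytest.approx(0.8)


def test_odd_count_median_and_m_folds_into_p():
    entries = [("s1", "A", 0.1, 0.0), ("s1", "A", 0.4, 0.5), ("s1", "A", 0.6, 1.0)]
    summary = phase_medians(_es_table(entries), _bands())
    # the 0.1 midpoint is an M window and folds into P
    assert summary.medians.loc["s1", ("A", "P")] == pytest.approx(0.5)


def test_cluster_without_q_windows_lacks_column():
    entries = [("s1", "A", 0.4, 0.5), ("s1", "A", 0.8, 0.7), ("s1", "B", 0.4, 0.2)]
    summary = phase_medians(_es_table(entries), _bands())
    assert ("B", "Q") not in summary.medians.columns
    assert ("A", "Q") in summary.medians.columns


def _summary_from_vectors(vectors):
    med = pd.DataFrame(vectors)
    med.columns = pd.MultiIndex.from_tuples(med.columns, names=["cluster", "phase"])
    return PhasePatternSummary(medians=med, grand_median=med.median(axis=0))


def test_identical_cluster_p_like_inverted_anti_p():
    rng = np.random.default_rng(1)
    ref_p = rng.random(12)
    ref_q = np.clip(ref_p * 0.3 + rng.random(12) * 0.1, 0, 1)
    summary = _summary_from_vectors(
        {
            ("A", "P"): ref_p,
            ("A", "Q"): ref_q,
            ("X", "P"): ref_p.copy(),       # identical to reference P
            ("Y", "P"): 1.0 - ref_p,        # inverted reference P
            ("Y", "Q"): 1.0 - ref_p,
        }
    )
    out = pattern_classify(summary, reference="A", r_threshold=0.3)
    lab = out.labels.set_index(["cluster", "phase"])["label"]
    corr = out.labels.set_index(["cluster", "phase"])["corr_ref_p"]
    assert lab[("A", "P")] == "P-like" and corr[("A", "P")] == pytest.approx(1.0)
    assert lab[("X", "P")] == "P-like" and corr[("X", "P")] == pytest.approx(1.0)
    assert lab[("Y", "P")] == "anti-P"
    assert lab[("Y", "Q")] == "anti-P"
    # correlation matrix is symmetric with unit diagonal
    c = out.correlations
    np.testing.assert_allclose(c.to_numpy(), c.to_numpy().T, atol=1e-12)
    np.testing.assert_allclose(np.diag(c.to_numpy()), 1.0)


def test_q_like_when_closer_to_reference_q():
    rng = np.random.default_rng(2)
    ref_p = np.linspace(0, 1, 10)
    ref_q = ref_p[::-1].copy()
    near_q = np.clip(ref_q + rng.normal(0, 0.05, 10), 0, 1)
    summary = _summary_from_vectors(
        {("A", "P"): ref_p, ("A", "Q"): ref_q, ("Z", "Q"): near_q}
    )
    out = pattern_classify(summary, reference="A")
    lab = out.labels.set_index(["cluster", "phase"])["label"]
    assert lab[("Z", "Q")] == "Q-like"


def test_labels_invariant_to_gene_set_order():
    rng = np.random.default_rng(3)
    vecs = {
        ("A", "P"): rng.random(8),
        ("A", "Q"): rng.random(8),
        ("B", "P"): rng.random(8),
    }
    s1 = _summary_from_vectors(vecs)
    out1 = pattern_classify(s1)
    perm = rng.permutation(8)
    s2 = PhasePatternSummary(
        medians=s1.medians.iloc[perm], grand_median=s1.grand_median
    )
    out2 = pattern_classify(s2)
    pd.testing.assert_frame_equal(out1.labels, out2.labels)


def test_too_few_gene_sets_rejected():
    summary = _summary_from_vectors(
        {("A", "P"): [0.1, 0.9], ("A", "Q"): [0.9, 0.1]}
    )
    with pytest.raises(ValueError, match="3 gene sets"):
        pattern_classify(summary)


def test_missing_reference_phase_rejected():
    summary = _summary_from_vectors({("A", "P"): [0.1, 0.5, 0.9]})
    with pytest.raises(ValueError, match="lacks phase"):
        pattern_classify(summary)


def test_q_boosted_programs_have_higher_q_medians(default_run):
    """Programs simulated with higher activity in the quiescent band come
    out with Q medians above P medians in the boosted sample's clusters."""
    result, truth, config = default_run
    med = result.summary.medians
    # clusters dominated by the resistant sample (where SYN_WNT_SIGNALING
    # is boosted 2.5x in Q)
    joint = pd.DataFrame(
        {"cluster": result.clusters.labels, "sample": truth["sample"]}
    )
    comp = joint.groupby("cluster")["sample"].agg(lambda s: (s == "resistant").mean())
    boosted_clusters = [
        c for c in comp.index[comp > 0.9]
        if ("c" != "" and (c, "P") in med.columns and (c, "Q") in med.columns)
    ]
    assert boosted_clusters, "no resistant-dominated cluster with both phases"
    checked = 0
    for c in boosted_clusters:
        p = med.loc["SYN_WNT_SIGNALING", (c, "P")]
        q = med.loc["SYN_WNT_SIGNALING", (c, "Q")]
        if not (np.isnan(p) or np.isnan(q)):
            assert q > p, (c, p, q)
            checked += 1
    assert checked >= 1
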