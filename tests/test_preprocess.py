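"""QC boundary behaviour, normalization arithmetic and clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from cellsync.io import CountMatrix
from cellsync.preprocess import (
    EmptyAfterQCError,
    cluster_cells,
    log_normalize,
    qc_filter,
    scale_genes,
)

from conftest import make_norm


def _counts(dense, cells=None, genes=None, symbols=None):
    dense = np.asarray(dense)
    n, g = dense.shape
    cells = cells or [f"c{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    return CountMatrix(
        sp.csr_matrix(dense),
        np.array(cells, object),
        np.array(genes, object),
        np.array(symbols, object) if symbols is not None else None,
    )


def test_gene_filter_boundary_three_cells():
    # gene0 in 2 cells -> removed; gene1 in 3 cells -> kept
    dense = np.array(
        [
            [1, 1, 1],
            [1, 1, 1],
            [0, 1, 1],
            [0, 0, 1],
        ]
    )
    out = qc_filter(_counts(dense), min_genes=1, max_genes=100)
    assert list(out.gene_ids) == ["g1", "g2"]
    assert out.n_cells == 4


def test_cell_filter_detected_gene_boundaries():
    n_genes = 4000
    rows = {
        "keep200": 200,
        "drop199": 199,
        "keep3700": 3700,
        "drop3701": 3701,
    }
    dense = np.zeros((4, n_genes), dtype=int)
    for i, k in enumerate(rows.values()):
        dense[i, :k] = 1
    out = qc_filter(_counts(dense, cells=list(rows)), min_cells_per_gene=0)
    assert list(out.cell_ids) == ["keep200", "keep3700"]


def test_cell_filter_mito_fraction_boundary():
    n_genes = 300
    symbols = ["MT-1"] + [f"S{j}" for j in range(1, n_genes)]
    keep = np.zeros(n_genes, dtype=int)
    keep[1:226] = 4          # 225 genes x 4 = 900
    keep[0] = 100            # mito fraction exactly 0.10
    drop = np.zeros(n_genes, dtype=int)
    drop[1:226] = 4
    drop[1] = 3              # total 999 + 101 mito
    drop[0] = 101            # fraction 101/1000 > 0.10
    m = _counts(np.vstack([keep, drop]), cells=["edge", "over"], symbols=symbols)
    out = qc_filter(m, min_cells_per_gene=0)
    assert list(out.cell_ids) == ["edge"]


def test_qc_empty_error_and_report():
    dense = np.ones((3, 10), dtype=int)
    with pytest.raises(EmptyAfterQCError):
        qc_filter(_counts(dense))  # only 10 detected genes each
    out, report = qc_filter(
        _counts(dense), min_genes=1, max_genes=100, return_report=True
    )
    assert report.n_cells_out == 3 and report.n_genes_out == 10


def test_log_normalize_hand_value():
    m = _counts([[1, 0]])
    norm = log_normalize(m, scale_factor=10)
    got = np.asarray(norm.values.todense()).ravel()
    np.testing.assert_allclose(got, [np.log(1 + 10), 0.0])


def test_log_normalize_depth_invariance_and_symmetry():
    m1 = _counts([[2, 3, 5], [4, 6, 10]])  # second cell = doubled first
    norm = log_normalize(m1)
    dense = np.asarray(norm.values.todense())
    np.testing.assert_allclose(dense[0], dense[1])
    m2 = _counts([[7, 7, 7]])
    row = np.asarray(log_normalize(m2).values.todense()).ravel()
    assert np.allclose(row, row[0])


def test_log_normalize_zero_total_rejected():
    with pytest.raises(ValueError, match="zero total"):
        log_normalize(_counts([[1, 2], [0, 0]]))


def test_scaled_matrix_centered():
    rng = np.random.default_rng(0)
    norm = make_norm(rng.lognormal(0, 1, (50, 20)))
    x = scale_genes(norm)
    assert np.abs(x.mean(axis=0)).max() < 1e-6
    assert np.abs(x).max() <= 10.0


def test_cluster_two_blobs_exact():
    rng = np.random.default_rng(1)
    nb = 200
    blob = np.vstack([rng.normal(0, 1, (nb, 50)), rng.normal(8, 1, (nb, 50))])
    counts = _counts(np.round(np.abs(blob) * 10).astype(int))
    norm = log_normalize(counts)
    ca = cluster_cells(norm, n_var_genes=50, n_pcs=10, seed=0)
    truth = np.array([0] * nb + [1] * nb)
    assert ca.sizes.size == 2
    assert adjusted_rand_score(truth, ca.labels.to_numpy()) == 1.0
    assert set(ca.labels.unique()) == {"A", "B"}


def test_cluster_identical_cells_single_cluster():
    norm = make_norm(np.full((40, 30), 2.0))
    ca = cluster_cells(norm, seed=0)
    assert ca.sizes.size == 1
    assert set(ca.labels) == {"A"}


def test_cluster_deterministic_and_permutation_consistent():
    rng = np.random.default_rng(2)
    x = np.vstack([rng.normal(0, 1, (60, 30)), rng.normal(6, 1, (60, 30))])
    norm = make_norm(np.abs(x))
    a = cluster_cells(norm, n_var_genes=30, n_pcs=5, seed=3)
    b = cluster_cells(norm, n_var_genes=30, n_pcs=5, seed=3)
    pd.testing.assert_series_equal(a.labels, b.labels)
    perm = rng.permutation(norm.n_cells)
    from cellsync.preprocess import NormalizedMatrix

    norm_p = NormalizedMatrix(
        norm.values[perm], norm.cell_ids[perm], norm.gene_ids, norm.gene_symbols
    )
    c = cluster_cells(norm_p, n_var_genes=30, n_pcs=5, seed=3)
    pd.testing.assert_series_equal(a.labels.sort_index(), c.labels.sort_index())


def test_cluster_too_few_cells_rejected():
    norm = make_norm(np.ones((5, 10)))
    with pytest.raises(ValueError, match="k_neighbors"):
        cluster_cells(norm, k_neighbors=20)
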