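"""Shared fixtures: simulated datasets and one full pipeline run.

The expensive artifacts (a default-condition simulation with its full
pipeline run, and a strong-effect scoring run) are session-scoped so the
recovery tests share one computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellsync.io import CountMatrix, GeneSetCollection
from cellsync.pipeline import run_pipeline
from cellsync.preprocess import NormalizedMatrix, log_normalize, qc_filter
from cellsync.simulate import SampleSpec, SimConfig, simulate_counts


FLAT_PROGRAMS = {
    name: {}
    for name in (
        "SYN_E2F_TARGETS", "SYN_TRANSLATION", "SYN_IFN_RESPONSE",
        "SYN_KRAS_SIGNALING", "SYN_EMT", "SYN_WNT_SIGNALING",
        "SYN_HEDGEHOG", "SYN_P53_PATHWAY",
    )
}


def make_norm(values: np.ndarray, cell_prefix: str = "c", gene_prefix: str = "g") -> NormalizedMatrix:
    """Wrap a dense array as a NormalizedMatrix with generated ids."""
    n, g = values.shape
    cells = np.array([f"{cell_prefix}{i:04d}" for i in range(n)], dtype=object)
    genes = np.array([f"{gene_prefix}{j:04d}" for j in range(g)], dtype=object)
    return NormalizedMatrix(sp.csr_matrix(values), cells, genes, genes.copy())


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_config):
    return simulate_counts(default_config)


@pytest.fixture(scope="session")
def default_run(default_config, default_sim):
    """Full pipeline on the default study conditions (2 x 1000 cells)."""
    matrix, truth = default_sim
    result = run_pipeline(
        matrix,
        default_config.cycle_gene_sets(),
        default_config.program_gene_sets(),
        seed=1,
    )
    truth = truth.set_index("cell_id").loc[result.norm.cell_ids]
    return result, truth, default_config


@pytest.fixture(scope="session")
def strong_config() -> SimConfig:
    """Strong-effect conditions: high cycle amplitude, low overdispersion,
    no dropout — the regime where phase programs dominate noise."""
    return SimConfig(
        samples=[SampleSpec("a", 500, 0.21), SampleSpec("b", 500, 0.61)],
        amplitude=3.0,
        dispersion=10.0,
        dropout=0.0,
        seed=2,
    )


@pytest.fixture(scope="session")
def strong_scored(strong_config):
    """QC + normalization + six-set scores on the strong-effect dataset."""
    from cellsync.cycle import assign_phase, score_gene_sets

    matrix, truth = simulate_counts(strong_config)
    norm = log_normalize(qc_filter(matrix))
    truth = truth.set_index("cell_id").loc[norm.cell_ids]
    scores = score_gene_sets(norm, strong_config.cycle_gene_sets(), seed=2)
    return scores, assign_phase(scores), truth


@pytest.fixture()
def small_counts() -> CountMatrix:
    rng = np.random.default_rng(0)
    values = rng.poisson(1.5, (30, 40))
    cells = np.array([f"bc{i:03d}" for i in range(30)], dtype=object)
    genes = np.array([f"ENSG{j:04d}" for j in range(40)], dtype=object)
    symbols = np.array([f"SYM{j}" for j in range(40)], dtype=object)
    return CountMatrix(sp.csr_matrix(values), cells, genes, symbols)


@pytest.fixture()
def six_sets() -> GeneSetCollection:
    return SimConfig().cycle_gene_sets()
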