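"""Generator properties: determinism, composition, program geometry."""

import numpy as np
import pandas as pd
import pytest

from cellsync.io import read_counts
from cellsync.simulate import (
    PHASE_ORDER,
    ConfigError,
    SampleSpec,
    SimConfig,
    expected_mean_counts,
    gene_table,
    simulate_counts,
    write_fixture,
)

from conftest import FLAT_PROGRAMS


def test_same_seed_identical_output():
    a, ta = simulate_counts(SimConfig(seed=7, samples=[SampleSpec("s", 150, 0.3)]))
    b, tb = simulate_counts(SimConfig(seed=7, samples=[SampleSpec("s", 150, 0.3)]))
    assert (a.values != b.values).nnz == 0
    pd.testing.assert_frame_equal(ta, tb)
    c, _ = simulate_counts(SimConfig(seed=8, samples=[SampleSpec("s", 150, 0.3)]))
    assert (a.values != c.values).nnz > 0


def test_g0_fraction_within_binomial_ci():
    """A 61%-quiescent sample of 2000 cells lands inside the binomial 99% CI."""
    q, n = 0.61, 2000
    cfg = SimConfig(samples=[SampleSpec("s", n, q)], seed=11)
    _, truth = simulate_counts(cfg)
    frac = (truth["true_phase"] == "G0").mean()
    half = 2.576 * np.sqrt(q * (1 - q) / n)
    assert abs(frac - q) <= half


def test_g0_fraction_law_of_large_numbers():
    cfg = SimConfig(
        samples=[SampleSpec("s", 5000, 0.4)], library_size=500, seed=13
    )
    _, truth = simulate_counts(cfg)
    assert abs((truth["true_phase"] == "G0").mean() - 0.4) < 0.02


def test_noise_free_limit_recovers_program_means():
    """Poisson noise + huge libraries: empirical per-gene means match the
    configured program means to within 5%."""
    cfg = SimConfig(
        samples=[SampleSpec("s", 80, 0.3)],
        dispersion=None,
        dropout=0.0,
        library_size=1e6,
        seed=5,
    )
    m, truth = simulate_counts(cfg)
    emp = np.asarray(m.values.todense(), float).mean(axis=0)
    exp = expected_mean_counts(cfg, truth).mean(axis=0)
    mask = exp > 50  # genes where Poisson noise at n=80 is far below 5%
    assert mask.sum() > 1000
    rel = np.abs(emp[mask] - exp[mask]) / exp[mask]
    assert rel.max() < 0.05


def test_cycle_program_peaks_follow_linearization():
    """Each cycle set's mean program peaks in the documented order
    G2M < M < MG1 < G1S < S < G0 along the pseudotime axis."""
    cfg = SimConfig(samples=[SampleSpec("s", 1, 0.0)], seed=0)
    grid = np.linspace(0.0, 1.0, 401)
    from cellsync.simulate import _relative_means

    rel = _relative_means(cfg, grid, np.array(["s"] * len(grid), object))
    genes = gene_table(cfg)
    argmax_pt = []
    for phase in PHASE_ORDER:
        cols = np.flatnonzero(
            (genes["kind"] == "cycle") & (genes["set_name"] == phase)
        )
        argmax_pt.append(grid[np.argmax(rel[:, cols].mean(axis=1))])
    assert argmax_pt == sorted(argmax_pt)
    assert argmax_pt[0] < 0.1 and argmax_pt[-1] > 0.9


def test_quiescent_cells_sit_above_the_cut():
    cfg = SimConfig(samples=[SampleSpec("s", 500, 0.5)], seed=3)
    _, truth = simulate_counts(cfg)
    g0 = truth["true_phase"] == "G0"
    assert (truth.loc[g0, "true_pseudotime"] >= cfg.quiescence_cut).all()
    assert (truth.loc[~g0, "true_pseudotime"] < cfg.quiescence_cut).all()


def test_cycle_sets_partition_the_cycle_genes():
    cfg = SimConfig()
    sets = cfg.cycle_gene_sets()
    sizes = [len(sets[p]) for p in PHASE_ORDER]
    assert sizes == [100, 100, 100, 100, 100, 103]
    allg = [g for p in PHASE_ORDER for g in sets[p]]
    assert len(allg) == len(set(allg)) == 603


def test_program_activity_multiplies_means():
    base = SimConfig(
        samples=[SampleSpec("s", 1, 0.0)], program_activity=FLAT_PROGRAMS, seed=0
    )
    boosted_programs = {k: dict(v) for k, v in FLAT_PROGRAMS.items()}
    boosted_programs["SYN_WNT_SIGNALING"] = {("s", "P"): 2.0}
    boosted = SimConfig(
        samples=[SampleSpec("s", 1, 0.0)], program_activity=boosted_programs, seed=0
    )
    from cellsync.simulate import _relative_means

    pt = np.array([0.4])  # P band
    s = np.array(["s"], object)
    genes = gene_table(base)
    cols = np.flatnonzero(genes["set_name"] == "SYN_WNT_SIGNALING")
    r0 = _relative_means(base, pt, s)[0, cols]
    r1 = _relative_means(boosted, pt, s)[0, cols]
    np.testing.assert_allclose(r1, 2.0 * r0)


def test_write_fixture_round_trip(tmp_path):
    cfg = SimConfig(
        samples=[
            SampleSpec("s1", 40, 0.2),
            SampleSpec("s2", 40, 0.5),
            SampleSpec("s3", 40, 0.8),
        ],
        library_size=800,
        seed=4,
    )
    m, truth = simulate_counts(cfg)
    write_fixture(
        m, truth, tmp_path,
        cycle_sets=cfg.cycle_gene_sets(),
        program_sets=cfg.program_gene_sets(),
    )
    back = read_counts(tmp_path)
    assert (back.values != m.values).nnz == 0
    samples = pd.read_csv(tmp_path / "samples.tsv", sep="\t")
    assert sorted(samples["sample"].unique()) == ["s1", "s2", "s3"]
    from cellsync.io import read_gmt

    assert len(read_gmt(tmp_path / "cycle_sets.gmt")) == 6
    assert len(read_gmt(tmp_path / "hallmark_like.gmt")) == 8


@pytest.mark.parametrize(
    "kwargs, match",
    [
        ({"samples": []}, "at least one sample"),
        ({"library_size": 0.0}, "library_size"),
        ({"dispersion": -1.0}, "dispersion"),
        ({"samples": [SampleSpec("s", 10, 1.2)]}, "quiescent_fraction"),
        ({"samples": [SampleSpec("s", 0, 0.2)]}, "no cells"),
        ({"dropout": 1.0}, "dropout"),
    ],
)
def test_invalid_configs_rejected(kwargs, match):
    with pytest.raises(ConfigError, match=match):
        SimConfig(**kwargs)
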