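"""Synthetic single-cell UMI count generator with known cell-cycle ground truth.

The generator emulates the population structure the pipeline is designed
to analyse: several isogenic samples, each a mixture of cycling cells and
a quiescent (G0) subpopulation of tunable prevalence.  Every cell carries
a latent *pseudotime* in [0, 1] encoding progression along a linearized
cell cycle: mitosis (G2M, M) near 0, growth and replication (MG1, G1S, S)
in the middle, quiescence (G0) at the top of the axis.

The five cycling gene sets are simulated as smooth unimodal "bump"
programs peaked at phase-specific pseudotime positions.  The G0 program
is different in kind: quiescence is a state, not a position on the
cycle, so its program switches on sigmoidally as cells cross the
quiescence cut and then deepens monotonically toward pseudotime 1 —
still unimodal with its peak at 1, but expressed in *every* quiescent
cell, shallow or deep, and essentially absent from cycling cells.  On top of
the cycle, a collection of hallmark-like functional programs is scaled
multiplicatively per (sample, phase-band), which is what creates
sample-level cluster structure and the band-dependent enrichment patterns
downstream stages are meant to recover.

Counts are drawn from a negative-binomial observation model (gene-specific
means, shared dispersion) with optional extra Bernoulli dropout; the
identical configuration and seed always yields the identical matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, GeneSetCollection, write_counts, write_gmt

__all__ = [
    "PHASE_ORDER",
    "PHASE_CENTERS",
    "SampleSpec",
    "SimConfig",
    "ConfigError",
    "simulate_counts",
    "expected_mean_counts",
    "gene_table",
    "write_fixture",
    "band_of_pseudotime",
]

#: Canonical phase order along the linearized cycle (also the argmax
#: tie-break order used by phase assignment downstream).
PHASE_ORDER = ("G2M", "M", "MG1", "G1S", "S", "G0")

#: Peak pseudotime of each phase's expression program.  Mitotic programs
#: peak near 0, the quiescence program at 1, growth programs in between.
PHASE_CENTERS = {"G2M": 0.04, "M": 0.14, "MG1": 0.30, "G1S": 0.46, "S": 0.60, "G0": 1.0}

_CYCLING = PHASE_ORDER[:5]

# Default hallmark-like functional programs and their activity multipliers.
# Keys of the inner maps are (sample role, band); band in {"M", "P", "Q"};
# missing entries default to 1.  Roles: "*" = every sample, "ref" = first
# sample (untreated-like), "alt" = every other sample (resistant-like).
_DEFAULT_PROGRAMS: dict[str, dict[tuple[str, str], float]] = {
    "SYN_E2F_TARGETS": {("*", "M"): 2.0, ("*", "P"): 2.0, ("*", "Q"): 0.4},
    "SYN_TRANSLATION": {("*", "Q"): 0.6, ("alt", "P"): 0.6},
    "SYN_IFN_RESPONSE": {("alt", "M"): 2.5, ("alt", "P"): 2.5, ("alt", "Q"): 2.5},
    "SYN_KRAS_SIGNALING": {("alt", "M"): 2.0, ("alt", "P"): 2.0, ("alt", "Q"): 2.0},
    "SYN_EMT": {("alt", "M"): 2.0, ("alt", "P"): 2.0, ("alt", "Q"): 2.0},
    "SYN_WNT_SIGNALING": {("alt", "Q"): 2.5},
    "SYN_HEDGEHOG": {("*", "Q"): 2.0},
    "SYN_P53_PATHWAY": {},
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SampleSpec:
    """One simulated sample: its label, size and quiescent prevalence."""

    name: str
    n_cells: int = 1000
    quiescent_fraction: float = 0.21


def _default_samples() -> list[SampleSpec]:
    # Untreated-like vs early-resistant-like quiescent prevalences.
    return [
        SampleSpec("untreated", 1000, 0.21),
        SampleSpec("resistant", 1000, 0.61),
    ]


@dataclass
class SimConfig:
    """Configuration of the synthetic population.

    Attributes
    ----------
    samples
        Sample descriptors (label, cell count, quiescent fraction each).
    n_cycle_genes
        Total cycle genes, partitioned across the six phase sets
        (603 splits as 100/100/100/100/100/103; the remainder goes to G0).
    n_program_genes
        Genes per functional program set.
    program_activity
        ``{set name: {(sample name, band): multiplier}}`` with band in
        {"M", "P", "Q"}; missing entries default to 1.  ``None`` installs
        the default hallmark-like programs resolved against ``samples``.
    library_size
        Mean UMI count per cell; per-cell depth varies lognormally
        (sd ``depth_sd`` on the log scale).
    dispersion
        Negative-binomial shape (var = m + m^2/dispersion); ``None``
        switches the observation model to Poisson.
    dropout
        Extra Bernoulli zero-inflation probability in [0, 1].
    amplitude, baseline_cycle, sigma_cycle
        Shape of the cycling bump programs: peak height over baseline
        and Gaussian width.
    g0_switch_width, g0_switch_offset, g0_depth_floor
        Shape of the quiescence program: a sigmoid of pseudotime centred
        at the quiescence cut (plus ``g0_switch_offset``) with the given
        width — half-activated exactly at cycle exit — multiplied by a
        depth ramp rising from ``g0_depth_floor`` at the cut to 1 at
        pseudotime 1.
    cut_m, quiescence_cut
        Pseudotime cuts defining the M / P / Q bands used for program
        activity and ground-truth bookkeeping.
    sample_effect_sd
        Lognormal sd of per-sample expression drift on the background
        genes — the global "clone identity" signature that makes each
        isogenic sample separable in expression space, as sibling clones
        are in real data.
    """

    samples: list[SampleSpec] = field(default_factory=_default_samples)
    n_cycle_genes: int = 603
    n_program_genes: int = 60
    program_activity: Mapping[str, Mapping[tuple[str, str], float]] | None = None
    library_size: float = 5000.0
    dispersion: float | None = 2.0
    dropout: float = 0.0
    seed: int = 0
    amplitude: float = 2.0
    baseline_cycle: float = 0.08
    sigma_cycle: float = 0.06
    g0_switch_width: float = 0.012
    g0_switch_offset: float = 0.0
    g0_depth_floor: float = 0.6
    n_background_genes: int = 800
    n_mito_genes: int = 10
    depth_sd: float = 0.25
    sample_effect_sd: float = 0.15
    cut_m: float = 0.20
    quiescence_cut: float = 0.69

    def __post_init__(self) -> None:
        if not self.samples:
            raise ConfigError("at least one sample is required")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate sample names")
        for s in self.samples:
            if not 0.0 <= s.quiescent_fraction <= 1.0:
                raise ConfigError(
                    f"quiescent_fraction of {s.name!r} must be in [0, 1]"
                )
            if s.n_cells <= 0:
                raise ConfigError(f"sample {s.name!r} has no cells")
        if self.library_size <= 0:
            raise ConfigError("library_size must be positive")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0 (or None for Poisson)")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError("dropout must be in [0, 1)")
        if self.n_cycle_genes < 6:
            raise ConfigError("need at least one gene per cycle set")
        if self.program_activity is None:
            self.program_activity = self._resolve_default_programs()
        for set_name, table in self.program_activity.items():
            for key, mult in table.items():
                if mult < 0:
                    raise ConfigError(
                        f"negative multiplier for {set_name}/{key}"
                    )

    def _resolve_default_programs(self) -> dict[str, dict[tuple[str, str], float]]:
        ref = self.samples[0].name
        alts = [s.name for s in self.samples[1:]]
        out: dict[str, dict[tuple[str, str], float]] = {}
        for set_name, table in _DEFAULT_PROGRAMS.items():
            resolved: dict[tuple[str, str], float] = {}
            for (role, band), mult in table.items():
                if role == "*":
                    targets = [s.name for s in self.samples]
                elif role == "ref":
                    targets = [ref]
                elif role == "alt":
                    targets = alts
                else:  # explicit sample name
                    targets = [role]
                for t in targets:
                    resolved[(t, band)] = mult
            out[set_name] = resolved
        return out

    # ---- derived gene architecture -------------------------------------

    def cycle_set_sizes(self) -> list[int]:
        base = self.n_cycle_genes // 6
        sizes = [base] * 6
        sizes[5] += self.n_cycle_genes - 6 * base
        return sizes

    def cycle_gene_sets(self) -> GeneSetCollection:
        """The six simulated cycle sets, keyed by phase name."""
        sets = {}
        for phase, size in zip(PHASE_ORDER, self.cycle_set_sizes()):
            sets[phase] = [f"CYC-{phase}-{i:03d}" for i in range(size)]
        return GeneSetCollection(sets, label="cycle_sets_synthetic")

    def program_gene_sets(self) -> GeneSetCollection:
        sets = {
            name: [f"{name}-{i:03d}" for i in range(self.n_program_genes)]
            for name in self.program_activity
        }
        return GeneSetCollection(sets, label="hallmark_like_synthetic")


def band_of_pseudotime(
    pt: np.ndarray, cut_m: float = 0.20, cut_q: float = 0.69
) -> np.ndarray:
    """Map pseudotime to the M / P / Q band labels (M: pt < cut_m,
    P: cut_m <= pt < cut_q, Q: pt >= cut_q)."""
    pt = np.asarray(pt, dtype=float)
    out = np.full(pt.shape, "P", dtype=object)
    out[pt < cut_m] = "M"
    out[pt >= cut_q] = "Q"
    return out


def gene_table(config: SimConfig) -> pd.DataFrame:
    """Per-gene architecture: id, kind and owning set of every simulated gene."""
    rows: list[tuple[str, str, str]] = []
    for phase, size in zip(PHASE_ORDER, config.cycle_set_sizes()):
        rows += [(f"CYC-{phase}-{i:03d}", "cycle", phase) for i in range(size)]
    for name in config.program_activity:
        rows += [
            (f"{name}-{i:03d}", "program", name)
            for i in range(config.n_program_genes)
        ]
    rows += [(f"MT-SYN{i}", "mito", "") for i in range(config.n_mito_genes)]
    rows += [(f"BG-{i:04d}", "background", "") for i in range(config.n_background_genes)]
    return pd.DataFrame(rows, columns=["gene_id", "kind", "set_name"])


def _gene_factors(config: SimConfig) -> np.ndarray:
    """Deterministic per-gene expression factors (lognormal heterogeneity)."""
    genes = gene_table(config)
    rng = np.random.default_rng([config.seed % (2**31), 11])
    fac = np.ones(len(genes))
    kind = genes["kind"].to_numpy()
    fac[kind == "cycle"] = rng.lognormal(0.0, 0.25, (kind == "cycle").sum())
    fac[kind == "program"] = rng.lognormal(0.0, 0.30, (kind == "program").sum())
    fac[kind == "mito"] = 2.0 * rng.lognormal(0.0, 0.20, (kind == "mito").sum())
    fac[kind == "background"] = rng.lognormal(
        np.log(0.3), 1.0, (kind == "background").sum()
    )
    return fac


def _bump(pt: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-((pt - center) ** 2) / (2.0 * sigma**2))


def _g0_activity(config: SimConfig, pt: np.ndarray) -> np.ndarray:
    """Quiescence-program activity: sigmoidal switch at the cut, then a
    monotone depth ramp to the peak of 1 at pseudotime 1."""
    cut = config.quiescence_cut
    switch = 1.0 / (
        1.0 + np.exp(-(pt - (cut + config.g0_switch_offset)) / config.g0_switch_width)
    )
    depth = config.g0_depth_floor + (1.0 - config.g0_depth_floor) * np.clip(
        (pt - cut) / max(1.0 - cut, 1e-12), 0.0, 1.0
    )
    return switch * depth


def _relative_means(
    config: SimConfig, pt: np.ndarray, sample: np.ndarray
) -> np.ndarray:
    """Relative (pre-depth) expression mean for every cell x gene."""
    genes = gene_table(config)
    fac = _gene_factors(config)
    n_cells, n_genes = len(pt), len(genes)
    rel = np.empty((n_cells, n_genes))

    kind = genes["kind"].to_numpy()
    set_name = genes["set_name"].to_numpy()

    # cycle genes: baseline + amplitude * per-gene factor * phase program
    for phase in PHASE_ORDER:
        if phase == "G0":
            prog = _g0_activity(config, pt)
        else:
            prog = _bump(pt, PHASE_CENTERS[phase], config.sigma_cycle)
        cols = np.flatnonzero((kind == "cycle") & (set_name == phase))
        rel[:, cols] = config.baseline_cycle + config.amplitude * np.outer(
            prog, fac[cols]
        )

    # functional program genes: per-gene factor * (sample, band) multiplier
    band = band_of_pseudotime(pt, config.cut_m, config.quiescence_cut)
    for name, table in config.program_activity.items():
        cols = np.flatnonzero((kind == "program") & (set_name == name))
        mult = np.ones(n_cells)
        for (smp, bnd), m in table.items():
            mult[(sample == smp) & (band == bnd)] = m
        rel[:, cols] = np.outer(mult, fac[cols])

    mito_cols = np.flatnonzero(kind == "mito")
    rel[:, mito_cols] = fac[mito_cols][None, :]

    # background genes carry a per-sample "clone identity" drift
    bg_cols = np.flatnonzero(kind == "background")
    rng = np.random.default_rng([config.seed % (2**31), 12])
    rel[:, bg_cols] = fac[bg_cols][None, :]
    for spec in config.samples:
        drift = rng.lognormal(0.0, config.sample_effect_sd, len(bg_cols))
        rows = np.flatnonzero(sample == spec.name)
        rel[np.ix_(rows, bg_cols)] *= drift[None, :]
    return rel


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a count matrix and its per-cell ground truth.

    Returns
    -------
    counts
        :class:`~cellsync.io.CountMatrix`, cells x genes.
    truth
        DataFrame with one row per cell: ``cell_id``, ``sample``,
        ``true_pseudotime`` (in [0, 1]), ``true_phase`` (one of
        :data:`PHASE_ORDER`), ``true_cluster`` (the sample label) and
        ``depth`` (the cell's sampled target library size).

    Quiescent cells (Bernoulli per sample with the configured
    ``quiescent_fraction``) receive pseudotime uniform on
    [``quiescence_cut``, 1] and phase G0; cycling cells receive
    pseudotime uniform on [0, ``quiescence_cut``) and the phase whose
    bump dominates at their position.
    """
    rng = np.random.default_rng([config.seed % (2**31), 17])

    cell_ids, sample_lbl, pt, phase = [], [], [], []
    cut_q = config.quiescence_cut
    # phase boundaries between cycling bumps (equal widths => midpoints)
    centers = [PHASE_CENTERS[p] for p in _CYCLING]
    bounds = [(a + b) / 2 for a, b in zip(centers, centers[1:])]
    for spec in config.samples:
        quiescent = rng.random(spec.n_cells) < spec.quiescent_fraction
        u = rng.random(spec.n_cells)
        cell_pt = np.where(quiescent, cut_q + u * (1 - cut_q), u * cut_q)
        idx = np.searchsorted(bounds, cell_pt)
        cell_phase = np.where(
            quiescent, "G0", np.array(_CYCLING, dtype=object)[idx]
        )
        for i in range(spec.n_cells):
            cell_ids.append(f"{spec.name}-{i:05d}")
        sample_lbl += [spec.name] * spec.n_cells
        pt.append(cell_pt)
        phase.append(cell_phase)

    pt = np.concatenate(pt)
    phase = np.concatenate(phase).astype(object)
    sample_lbl = np.asarray(sample_lbl, dtype=object)

    rel = _relative_means(config, pt, sample_lbl)
    depth = config.library_size * rng.lognormal(
        -0.5 * config.depth_sd**2, config.depth_sd, len(pt)
    )
    mean = rel * (depth / rel.sum(axis=1))[:, None]

    if config.dispersion is None:
        counts = rng.poisson(mean)
    else:
        r = config.dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    if config.dropout > 0:
        counts = np.where(rng.random(counts.shape) < config.dropout, 0, counts)

    genes = gene_table(config)
    matrix = CountMatrix(
        sp.csr_matrix(counts),
        np.asarray(cell_ids, dtype=object),
        genes["gene_id"].to_numpy(dtype=object),
    )
    truth = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "sample": sample_lbl,
            "true_pseudotime": pt,
            "true_phase": phase,
            "true_cluster": sample_lbl,
            "depth": depth,
        }
    )
    return matrix, truth


def expected_mean_counts(config: SimConfig, truth: pd.DataFrame) -> np.ndarray:
    """Noise-free expected counts (cells x genes) for a simulated draw.

    Uses the cells' latent pseudotime, sample and sampled depth from
    ``truth``; the observation model (NB/Poisson, dropout) is mean-
    preserving up to the dropout factor, which is applied here.
    """
    rel = _relative_means(
        config,
        truth["true_pseudotime"].to_numpy(),
        truth["sample"].to_numpy(dtype=object),
    )
    mean = rel * (truth["depth"].to_numpy() / rel.sum(axis=1))[:, None]
    return mean * (1.0 - config.dropout)


def write_fixture(
    matrix: CountMatrix,
    truth: pd.DataFrame,
    dir: str | Path,
    cycle_sets: GeneSetCollection | None = None,
    program_sets: GeneSetCollection | None = None,
) -> None:
    """Write a simulated dataset as plain-text files under ``dir``.

    Emits the matrix-market triplet, ``truth.tsv`` (which doubles as the
    per-cell sample-label table) and, when provided, the GMT files of the
    simulated gene-set collections.  Round-trips losslessly through
    :func:`cellsync.io.read_counts`.
    """
    dir = Path(dir)
    dir.mkdir(parents=True, exist_ok=True)
    write_counts(matrix, dir)
    truth.to_csv(dir / "truth.tsv", sep="\t", index=False)
    truth[["cell_id", "sample"]].to_csv(dir / "samples.tsv", sep="\t", index=False)
    if cycle_sets is not None:
        write_gmt(cycle_sets, dir / "cycle_sets.gmt")
    if program_sets is not None:
        write_gmt(program_sets, dir / "hallmark_like.gmt")
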