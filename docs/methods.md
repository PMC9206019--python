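# Methods

This note documents the models, parameter choices and numerical details
behind `cellsync`, and what the synthetic validation does and does not
demonstrate about real data.

## The analysis model

The pipeline treats the cell cycle plus quiescence as a *linear* axis:
mitosis → growth/replication → quiescence. This is deliberate — the
populations of interest contain a substantial G0 compartment, and a cell
leaving mitosis either cycles onward or exits into deepening quiescence,
so a line (not a circle) is the right topology for comparing
proliferative and quiescent states. The axis is never interpreted as
wall-clock time; it is an ordering statistic.

All stages operate on depth-normalized log expression
`x = ln(1 + c/C · s)` with scale factor `s = 10⁴`. Zero counts map to
exactly zero, and the normalization is exactly invariant to per-cell
depth scaling.

### QC filters

Cell metrics (detected genes, mitochondrial fraction) are computed on
the **original** gene universe; cells are removed first, then genes seen
in fewer than 3 surviving cells. The thresholds act strictly: cells with
exactly 200 or 3700 detected genes, or exactly 10% mitochondrial
counts, are kept. Running the filter twice with the same universe
definition is idempotent. Mitochondrial genes are recognized by the
symbol prefix `MT-` (configurable).

### Clustering

Variable genes are ranked by a mean-binned dispersion z-score (variance
over mean on the linear scale, z-scored within 20 equal-frequency bins
of the mean), the top 2000 standardized and clipped at ±10, reduced to
50 principal components, and a k = 20 nearest-neighbour graph is
partitioned with multilevel Louvain at resolution 0.2. Only variable
genes are scaled and fed to PCA; this is configurable but is the
default because it bounds the influence of the invariant majority of
genes. Cells are processed in sorted-id order and the igraph RNG is
seeded, so results are reproducible and permutation-consistent. Labels
are letters by decreasing size, ties broken by the smallest contained
cell position in the canonical order.

### Phase scoring

Each cell is scored against an arbitrary number of cycle gene sets (six
here) with a bin-matched module score: genes are cut into 24
equal-frequency bins of mean expression, and each set gene contributes
100 control draws (with replacement) from the non-set genes of its bin.
Excluding the set's own genes from the control pool keeps the score an
unbiased contrast even when a set dominates its expression bins; when a
bin contains nothing but set genes the full bin is used as the only
available pool. Control draws are seeded per set (global seed plus a
hash of the set name), so adding sets does not perturb existing scores.
The assigned phase is the argmax over set scores; exact ties resolve to
the earlier phase in the order G2M, M, MG1, G1S, S, G0, and every cell
receives a phase even when all scores are negative (an "undecided"
class would silently change downstream composition statistics).

Percentages in composition tables are truncated, not rounded, at the
displayed precision (one decimal below 10%, integer above).

### Pseudotime

On the union of the cycle sets: pairwise distance `1 − ρ_Spearman`
between cell profiles, classical (Torgerson) MDS to 3 components with a
deterministic eigenvector sign convention, k-means (k = 4) centroids
ordered by the exhaustive shortest open Hamiltonian path, then
principal-curve refinement: project cells onto the current polyline,
lowess-smooth each embedding coordinate against arc-length (span 0.2,
0 robustness iterations), and repeat until the mean projection shift
falls below 1e-4 of the embedding scale or 50 iterations. Pseudotime is
the arc-length position min–max rescaled to [0, 1], flipped if needed
so that cells rich in G2M/M expression average lower than cells rich in
G0 expression (anchor sets configurable). Cells are processed in
sorted-id order, making the result exactly invariant to input order.

The rank-based distance bounds resolution by the number of cycle genes:
two cells whose cycle-gene *ranking* is identical are equidistant from
everything and their relative order is arbitrary. This matters only in
saturated extremes of the axis.

### Bands and windows

The three-band view (M: mitosis, P: growth/proliferation,
Q: quiescence) uses cuts at pt = 0.20 and 0.69 by default. The cuts can
instead be derived from the data: pt is cut into 0.05-wide bins, each
non-empty bin labelled by the phase super-group ({G2M, M} / {MG1, G1S,
S} / {G0}) holding a strict majority (> 50%), and the cuts placed at
the seams of a clean M→P→Q block structure (mixed bins tolerated at the
seams; the seam falls at the shared edge, or mid-gap). If no clean
changepoint structure exists the fixed defaults are used with a
warning. S-phase cells belong to the growth super-group.

Windows slide over the **global** [0, 1] range for every cluster
(interval 0.2, increment 0.01 → 81 windows; membership
`start ≤ pt < end`, with pt = 1 closed into the final window), so
window columns are comparable across clusters. Windows with fewer than
5 member cells are dropped, not errors — a "virtual cell" of 2 cells is
not an aggregate.

### Virtual cells

Stage 1 per (cluster, window): the per-gene shifted geometric mean
`exp(mean(ln(1 + x))) − 1` over member cells, computed on linear-scale
depth-normalized expression. The shift is essential: a raw geometric
mean is annihilated by a single zero count, which at scRNA-seq sparsity
would zero out most of the table. Stage 2 divides each gene by its
median over all (cluster, window) columns pooled across clusters —
pooling is what makes the resulting ratios comparable across clusters,
at the cost of coupling them. Genes whose across-table median is zero
are excluded (logged) rather than divided by a floor; a ratio against
an arbitrary epsilon is noise dressed as signal. Stage 3 is
`log2(1 + ratio)`.

### Enrichment and scaling

Single-sample GSEA of each virtual cell against each functional set:
genes sorted by descending value with ties broken by gene identifier
(platform-independent), weights `|N − i + 1|^α` on the rank scale with
α = 0.75 (α = 0 reduces to a pure rank statistic, exactly invariant to
monotone transforms of the profile; value-weighting is available). The
running sum satisfies `P_in(N) = P_out(N) = 1` exactly, which the tests
assert. Scores are min–max scaled to [0, 1] per gene set across the
whole table; a constant set scales to 0.5 with a warning. Per-set
scaling (rather than global) is used because the downstream medians
compare each program against its own dynamic range.

### P/Q medians and patterns

Medians are taken over windows (a window's phase is its midpoint's
band; M-band windows fold into P, matching the two-phase P/Q
vocabulary). A cell-count-weighted variant is available but windows are
the default unit, since enrichment is computed per window. Each
(cluster, phase) median vector over gene sets is Pearson-correlated
(Spearman by flag) with the reference cluster's P and Q vectors and
labelled: P-like if the P correlation is the larger and ≥ 0.3, Q-like
if the Q correlation is the larger and ≥ 0.3, anti-P if the P
correlation ≤ −0.3, otherwise unclassified. The 0.3 threshold separates
"correlated" from background; it is a reported parameter, not a claim
about significance, and no hypothesis testing is attached to the
labels.

## The synthetic generator

The generator emulates the population structure the pipeline targets:

* several isogenic samples, each a mix of cycling cells and a quiescent
  subpopulation of configurable prevalence (defaults 21% and 61% for an
  untreated-like and a resistant-like sample, 1000 cells each);
* 603 cycle genes partitioned into six sets
  (100/100/100/100/100/103). The five cycling sets are Gaussian bumps
  along pt (centers 0.04, 0.14, 0.30, 0.46, 0.60; width 0.06; amplitude
  2.0 over a 0.08 baseline). The G0 set is a *state* program, not a
  position bump: a sigmoid switch centred at the quiescence cut
  (width 0.012) times a depth ramp rising from 0.6 at the cut to 1 at
  pt = 1 — every quiescent cell expresses it, shallow or deep, and
  cycling cells essentially do not. Latent pt is uniform on [0, 0.69)
  for cycling cells and [0.69, 1] for quiescent ones;
* eight hallmark-like functional programs of 60 genes whose means are
  multiplied per (sample, band) — e.g. a quiescence-band-only induction
  — giving downstream enrichment something with known structure to
  recover;
* 800 background genes with lognormal mean heterogeneity, carrying a
  per-sample lognormal drift (sd 0.15 on the log scale) that emulates
  the global "clone identity" differences between isogenic samples and
  makes clusters track samples rather than splitting purely by phase;
* 10 mitochondrial (`MT-`) genes, lognormal per-cell depths (mean 5000
  UMIs, sd 0.25), negative-binomial counts with shared dispersion 2.0
  (`None` switches to Poisson), optional Bernoulli dropout (default 0 —
  the NB at these depths already produces realistic sparsity).

What it does **not** emulate: doublets, batch effects, copy-number
heterogeneity, gene–gene correlation beyond the shared programs,
transcriptional bursting, or a circular (re-entrant) cycle topology.
Passing the recovery tests therefore shows the pipeline is correct and
well-conditioned under its own modelling assumptions — not that those
assumptions hold in any particular real dataset.

## Problem sizes and numerical conventions

The validation suite runs the full pipeline at 2000 cells (default
conditions) and scores phases at 1000 cells under a strong-effect
configuration (amplitude 3.0, dispersion 10, no dropout) — sizes chosen
so the whole suite completes in well under a minute of compute per
stage while keeping binomial noise on recovered fractions around one
percentage point. Reproducibility conventions: every stochastic step
(simulation, control draws, k-means, Louvain) derives from an explicit
integer seed; module-score streams are seeded per gene set; cell-order
canonicalization plus fixed tie-breaks (gene identifier in the ssGSEA
sort, earlier-phase on score ties, smallest-position on cluster-size
ties) make equal inputs give byte-equal outputs.

## Known limitations

* The linear trajectory cannot represent cycle re-entry; datasets
  dominated by continuously cycling cells with no quiescent arm would
  be better served by a circular embedding.
* Classical MDS is O(n²) memory in cells; the intended scale
  (thousands of cells after per-cluster analysis) fits comfortably, but
  a landmark approximation would be needed far beyond that.
* Pattern labels depend on the reference cluster containing both P and
  Q windows; a reference with no quiescent arm yields medians only.
* The derived band cuts require a clean M→P→Q changepoint structure;
  noisy phase assignments near the quiescence boundary can push the
  derivation to the fixed-cut fallback (it warns when it does).
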