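# cellsync

Virtual synchronization of single-cell RNA-seq data along a linear
cell-cycle pseudotime.

## The problem

Cell populations under cytotoxic stress — for example ovarian cancer
clones acquiring platinum resistance — shift their balance between
proliferation and quiescence. That shift confounds expression analysis:
a gene program that merely tracks the cell cycle looks "differentially
expressed" in bulk whenever the proliferative fraction changes.
`cellsync` removes this confounder the way one would with a physical
synchronization experiment, but computationally: it orders
unsynchronized cells along a linear cell-cycle pseudotime
*pt* ∈ [0, 1] running from mitosis (G2M, M), through growth and
replication (MG1, G1S, S), into quiescence (G0), and then compares
gene-program activity between cells at comparable cycle positions
across samples or clusters.

The package is aimed at analysts working with 10x-style UMI count
matrices who want the full chain — QC, clustering, multi-set cell-cycle
phase scoring, trajectory, windowed "virtual cells", per-window
single-sample GSEA and proliferation/quiescence pattern calls — as
composable, tested library functions, plus a synthetic-data generator
with known ground truth to validate every stage.

## Method

1. **QC and normalization.** Genes seen in < 3 cells are dropped; cells
   with < 200 or > 3700 detected genes, or > 10% mitochondrial counts,
   are removed (boundary cells are kept). Counts are depth-normalized
   and log-transformed: `x = ln(1 + c / C · 10⁴)`.
2. **Clustering.** Dispersion-ranked variable genes → standardized,
   clipped at ±10 → PCA (50 components) → kNN graph (k = 20) →
   multilevel Louvain at resolution 0.2. Clusters are lettered A, B, C…
   by decreasing size.
3. **Phase scoring.** Each cell is scored against six cell-cycle gene
   sets with an expression-bin-matched module score,
   `score = mean(set genes) − mean(bin-matched controls)`, and assigned
   the argmax phase among {G2M, M, MG1, G1S, S, G0}.
4. **Pseudotime.** On the union of the cycle genes: cell–cell distance
   `d = 1 − ρ_Spearman`, classical MDS to 3 components, an initial path
   through k-means centroids, principal-curve refinement, arc-length
   position rescaled to [0, 1], oriented so mitotic cells sit low.
5. **Bands and windows.** The axis splits into mitosis / proliferation /
   quiescence bands (default cuts 0.20 and 0.69, or derived from
   bin-majority changepoints). Per cluster, cells are grouped in sliding
   windows (interval 0.2 of the pt range, increment 0.01 — 81 windows).
6. **Virtual cells.** Each window collapses to one profile: the per-gene
   shifted geometric mean `exp(mean(ln(1 + x))) − 1`, divided by the
   gene's median across all windows and clusters, then log2-transformed.
7. **Enrichment.** Every virtual cell is scored against a functional
   (hallmark-style) collection with single-sample GSEA
   (`ES = Σᵢ (P_in(i) − P_out(i))`, rank weights `|N − i + 1|^α`,
   α = 0.75), and each gene set's scores are min–max scaled to [0, 1]
   across all windows and clusters.
8. **P/Q patterns.** Scaled scores are summarized as per-(cluster,
   phase) medians over P (pt < cut) and Q (pt ≥ cut) windows, and each
   cluster/phase activity vector is classified against a reference
   cluster as *P-like*, *Q-like*, *anti-P* (strong negative correlation
   with reference-P) or unclassified.

## Worked example

Simulate the default study conditions — an untreated-like sample (21%
quiescent) and a resistant-like sample (61% quiescent), 1000 cells each
— and run the full pipeline:

```python
import numpy as np
from scipy.stats import spearmanr
from cellsync import SimConfig, simulate_counts, run_pipeline, format_percent

config = SimConfig(seed=1)                      # 2 samples x 1000 cells
counts, truth = simulate_counts(config)
result = run_pipeline(
    counts, config.cycle_gene_sets(), config.program_gene_sets(), seed=1
)

truth = truth.set_index("cell_id").loc[result.norm.cell_ids]
rho = spearmanr(result.pseudotime.pt, truth["true_pseudotime"])[0]
print(f"cells passing QC:        {result.norm.n_cells}")
print(f"clusters (by size):      {result.clusters.sizes.to_dict()}")
print(f"pseudotime recovery rho: {abs(rho):.3f}")
print(f"band cuts (M/P, P/Q):    {result.bands.cut_m:.2f}, {result.bands.cut_q:.2f}")
print(f"quiescent band fraction: {format_percent((result.bands.band == 'Q').mean())}")
print(result.summary.labels.to_string(index=False))
```

Output:

```
cells passing QC:        2000
clusters (by size):      {'A': 609, 'B': 386, 'C': 370, 'D': 258, 'E': 211, 'F': 166}
pseudotime recovery rho: 0.975
band cuts (M/P, P/Q):    0.20, 0.85
quiescent band fraction: 38%
cluster phase  corr_ref_p  corr_ref_q        label
      A     P    1.000000    0.993895       P-like
      A     Q    0.993895    1.000000       Q-like
      B     P   -0.437009   -0.474767       anti-P
      C     P   -0.924490   -0.949766       anti-P
      D     P    0.271649    0.253933 unclassified
      D     Q    0.031038    0.005684 unclassified
      E     P    0.199776    0.258551 unclassified
      E     Q    0.093894    0.165354 unclassified
      F     P   -0.871161   -0.914395       anti-P
      F     Q   -0.878833   -0.923688       anti-P
```

Reading the output: the inferred pseudotime tracks the latent cycle
position (|ρ| = 0.975); the derived quiescence cut at pt = 0.85 puts 38%
of cells in the quiescent band versus the 41% simulated; and the pattern
table flags clusters whose median program activity is strongly
anti-correlated with the reference cluster's proliferative state
(*anti-P*) — the signature of a broadly repressed, quiescence-like
expression state.

The same workflow is available from the shell:

```bash
cellsync simulate --out data/ --seed 1
cellsync run-all --counts data/ --gmt-cycle data/cycle_sets.gmt \
    --gmt-hallmark data/hallmark_like.gmt --out results/ --seed 1
```

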