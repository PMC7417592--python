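# ascpath

Division-resolved analysis of B-cell differentiation into antibody-secreting
cells (ASCs), for computational immunologists studying how proliferating,
LPS-activated B cells split into an ASC-destined branch and a non-ASC branch.

When naive B cells respond to a T-independent antigen they divide up to ~8
times (tracked with a dilution dye such as CellTrace Violet), grow their
total mRNA content with each division, and — somewhere after activation —
bifurcate: one branch loses CD62L (*Sell*), switches on the plasma-cell
program (*Prdm1*, *Xbp1*, *Irf4*, *Sdc1*) together with OXPHOS/MYC metabolic
modules and becomes CD138⁺ ASC at division 8; the other retains B-cell
identity and up-regulates inflammatory genes. `ascpath` implements the
computational chain that resolves this structure from sequencing data, and a
synthetic data generator with known ground truth to exercise and validate
every stage:

- **Bulk absolute quantification** — reads-per-million scaling, the
  per-group detection filter (RPM ≥ 3 in every sample of at least one
  group), and ERCC spike-in conversion to absolute transcript counts,

  mRNA_A / cell = (FPKM_A / N_cells) × (Σ molecules_ERCC / Σ FPKM_ERCC),

  plus total mRNA content per sample and differential-expression flagging
  (|log₂FC| > 1, Benjamini–Hochberg FDR < 0.05; the BH step-up is
  implemented here).
- **Single-cell QC and normalization** — genes expressed in < 10 cells and
  cells with < 1000 total UMI removed in a single pass; median library-size
  + square-root normalization for imputation, CP10K + log1p for clustering.
- **Markov diffusion imputation** — adaptive Gaussian kernel on a kNN graph
  in PCA space, symmetrized and row-normalized to a transition operator P;
  imputed expression is Pᵗ·X (defaults k = 30, ka = 10, t = 3).
- **Reference KNN annotation** — single cells are merged with
  division-sorted bulk reference profiles (divisions 0, 1, 3, 5, 8⁻, 8⁺) on
  shared gene symbols, quantile normalized jointly, and labeled by plurality
  vote of the k nearest reference replicates.
- **Branching pseudotime** — density-peak clustering (ρ/δ decision rule),
  ordering-gene selection by across-cluster Kruskal–Wallis with BH q-values,
  a principal tree fitted as the minimum spanning tree over cluster
  centroids with cells projected onto edges, pseudotime as tree geodesic
  from the root, and branches as maximal branch-point-free segments.
- **Preranked GSEA** — genes ranked by sign(FC) × (1 − p); weighted
  Kolmogorov–Smirnov enrichment score with a seeded gene-label permutation
  null, p = (1 + #{|ES_perm| ≥ |ES|}) / (n_perm + 1); leading-edge
  extraction and mean-cubed per-cell activity scores.
- **Regulon activity** — AUCell-style recovery AUC of transcription-factor
  target sets in each cell's top-ranked genes, Pearson correlation of
  activity change vs factor-expression change between cell groups, and
  AP-1 / AICE / other motif-class partitions.

## Worked example

Run the full chain on the default synthetic experiment (2000 cells, 1500
genes, divisions 0–8 with a bifurcation at division 3):

```bash
ascpath run --seed 1 --outdir out/
```

which prints (abridged):

```json
{
  "n_cells_after_qc": 2000,
  "n_clusters": 16,
  "n_branch_points": 1,
  "n_branches": 3,
  "branch_ari_vs_truth": 0.8677,
  "cell_type_accuracy": 0.9425,
  "division_within_one": 0.835,
  "activity_expression_pearson_r": 0.9435,
  "enrichment": {
    "oxphos":  {"es":  0.958, "p_value": 0.000999},
    "inflam":  {"es": -0.980, "p_value": 0.000999},
    "bcell":   {"es": -0.966, "p_value": 0.000999}
  }
}
```

Reading the numbers: the trajectory stage found exactly one branch point and
three branches whose cell assignment agrees with the generating lineage at
adjusted Rand index 0.87; KNN annotation against the simulated bulk panel
recovers the cell type (nB/actB/ASC) for 94% of cells and places 84% within
one division of the truth; the OXPHOS/MYC module is enriched on the
ASC-destined branch and the inflammatory and B-cell-identity modules on the
non-ASC branch, each at the permutation floor p = 1/1001; and regulon
activity changes track factor expression changes at Pearson r = 0.94.

Each stage is also an importable function (`ascpath.simulate_experiment`,
`ascpath.molecules_per_cell`, `ascpath.gsea_preranked`, ...) and a CLI
subcommand (`simulate`, `preprocess`, `impute`, `annotate`, `trajectory`,
`gsea`, `regulon`, `run`). Formats: 10x-style MTX triplets, TSV matrices,
GMT gene sets, YAML/JSON configs.

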