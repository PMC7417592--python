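# Methods

## The synthetic experiment

The generator (`ascpath.simulate`) emulates the statistical structure of a
division-tracked, LPS-driven B-cell response profiled by droplet scRNA-seq,
with matched division-sorted bulk profiles. It is the test bed for the whole
pipeline: every recovery claim in the test suite is a claim about data with
this structure.

**Cell states.** Each cell carries a division index d ∈ {0..8} (occupancy
triangular with its peak at division 5, plus a retained undivided pool — the
shape of a dye-dilution histogram 72 h after stimulation; configurable via
`division_weights`), a lineage branch and a state. Cells below the
commitment division (default 3) are *pre-branch*; from division 3 onward a
cell is ASC-destined with probability `asc_fraction` (default 0.5),
otherwise non-ASC. ASC-destined cells reaching division 8 acquire the
terminal ASC state; a fraction `er_stress_fraction` (default 0.3) of those
enters an ER-stress sub-state that differs from plain ASC only in an
ER-chaperone module.

**Expression programs.** A baseline mean vector is drawn log-normally
(σ = 1) over `n_genes` (default 1500) genes, of which seven marker modules
are carved out (ASC 60, B-cell identity 30, OXPHOS/MYC 80, inflammatory 60,
ER-chaperone 40, naive/resting 40, proliferation 60 genes; leading members
carry readable aliases such as `Prdm1_like`, `Sell_like`, `Mki67_like`).
With a = d/8 the shared activation ramps and with
r = 0.15 + 0.85·((d − 3)/5)² the branch ramp, the multipliers are:

| program | cells affected | factor |
|---|---|---|
| proliferation/biosynthesis | all | 1 + 16a |
| metabolic activation (OXPHOS/MYC) | all | 1 + 2a |
| naive/resting | all | 1 + 4(1 − a), ×1.5 more in undivided nB |
| ASC module | ASC-destined | 1 + 7r, ×3 more in the terminal state |
| OXPHOS/MYC extra | ASC-destined | 1 + 4r |
| Sell-analog / B-cell identity | ASC-destined | 1 − 0.95r |
| inflammatory | non-ASC | 1 + 8r |
| ER chaperones | ASC-ER-stress | ×6 |

The branch ramp is convex with a small jump at commitment: fate choice is
modeled as a discrete switch (the IRF4-high/-low decision) followed by
maturation that accelerates toward division 8. This matches two properties
of the real system that the pipeline depends on: bulk profiles sorted by
division are dominated by division-covarying programs (so reference KNN can
anchor division identity even though mid-ladder sorted pools mix both
branches), while the terminal secretory program dwarfs everything else only
at the end of the ladder.

**Counts.** Expected expression is the program mean times the total-mRNA
growth factor `mrna_scale_per_division`^d (default 1.3, so a division-8 cell
carries ~8× the mRNA of a naive cell before branch effects) times a per-cell
log-normal capture efficiency (CV `libsize_cv` = 0.3) shared by genes and
spike-ins — shared capture is what makes spike-based absolute quantification
recoverable. UMI counts are negative-binomial with Var = m + 0.1·m²; the
baseline library is ~3000 UMI at division 0. Thirty ERCC-like spikes form a
fixed geometric pool contributing ~10% of a division-0 library, so the spike
share of each cell's counts falls as divisions accumulate mRNA. Program
totals are *not* renormalized after module effects: the terminal secretory
load adds to total mRNA content on top of the division factor, as it does in
differentiating ASCs.

**Bulk panel.** For each reference label (0, 1, 3, 5, 8⁻, 8⁺) the panel
emits `bulk_replicates` (default 3) replicate profiles of 1000-cell pools:
the label's program mean — an `asc_fraction`-weighted mixture of the two
branch programs for mid-ladder divisions, since sorting is by division
only — perturbed by per-gene log-normal noise (sdlog `bulk_noise_sd` = 0.15),
with spike rows included. Synthetic regulons pick marker genes as factors
and draw their targets from the factor's own module, so regulon activity
co-varies with factor expression by construction; motif annotations are
tagged AICE:AP-1 ≈ 65:35 with ~10% "other".

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing-read noise, UMI collisions,
ambient RNA, doublets, batch effects between the single-cell and bulk
modalities beyond what quantile normalization absorbs, gene length (FPKM and
RPM coincide; spike and gene "lengths" are equal by construction),
cell-cycle phase structure within a division, and dropout beyond what the
negative binomial induces.

## Stage-by-stage choices

**Bulk normalization.** RPM uses biological genes in the per-million
denominator; spike rows are carried along with the same factor (the spike
sum of the absolute-quantification ratio is the only place spikes enter).
The detection rule — RPM ≥ 3 in *every* sample of at least one group — is
evaluated per group, never pooled. BH-FDR is a hand-rolled step-up
(cumulative minimum from the largest p), cross-checked in the tests against
`statsmodels.stats.multitest`. The default differential test is a per-gene
two-sample Wilcoxon rank-sum on log₂(RPM + 1) — assumption-light plumbing;
any per-gene (log2fc, p) table can be substituted.

**QC and normalization.** Both QC rules are evaluated on the input matrix
in one pass (not iterated), so the result is idempotent but not a fixed
point of alternating filters. "Expressed" means count > 0. Library-size
targets: the median library for the sqrt path, 10⁴ for the log path —
the conventional targets of the respective downstream methods.

**Diffusion imputation.** kNN (k = 30) in the top 20 PCs of the
sqrt-normalized matrix; Gaussian kernel with per-cell bandwidth equal to the
distance to the ka = 10-th neighbor; kernel symmetrized by addition; rows
normalized. Neighbor queries keep all ties at the k-th-neighbor distance so
duplicate cells receive identical operator rows. The operator is dense —
adequate to ~5000 cells — and persistable (TSV + JSON). t = 3 diffusion
steps by default; t = 0 is the identity, and powers compose exactly
(Pᵗ¹⁺ᵗ² X = Pᵗ²(Pᵗ¹X)).

**KNN annotation.** Cells and reference replicates are merged on exact
gene-id matches and quantile normalized jointly (classic rank-mean scheme;
ties within a column receive the mean of their positions' rank-means).
Distances are Euclidean over all shared genes. k defaults to the replicate
count of the smallest label class. Vote ties break by smaller mean distance
among the tied labels, then lexicographically — fully deterministic.

**Clustering.** Density peaks with a hard-count kernel: d_c is the
max(1%, 20/n) quantile of all pairwise distances — the floor keeps ≥ ~20
neighbors in the kernel for small datasets, where a 1% kernel makes the
density estimate too noisy. Centers are density peaks (ρ ≥ 1) whose nearest
denser cell lies beyond 1.5·d_c, ranked by the decision-graph product
γ = ρ·δ and capped at 16. A joint high-percentile threshold on ρ and δ was
rejected: on an elongated differentiation manifold the density varies
along and between arms, and a global ρ threshold silently discards the
peaks of the sparser arms, collapsing the trajectory to a path. The
separation-gated, γ-ranked rule keeps one-per-mode behavior on well-separated
isotropic clusters (one blob → one cluster; three blobs → three) while
resolving a chain of centers along each trajectory arm. Remaining cells
join their nearest denser neighbor's cluster, in descending density order.

**Ordering genes.** Across-cluster Kruskal–Wallis per gene (constant genes
get p = 1), BH q-values, top 1000 by ascending q with p and then descending
H as tie-breaks.

**Principal tree.** PCA (num_dim = 10) of the ordering-gene submatrix;
cluster centroids as nodes; minimum spanning tree over centroid distances;
each cell orthogonally projected to its nearest tree edge; pseudotime =
geodesic distance from the root node to the projection. The root is the
cluster richest in division-0/naive-annotated cells (or user-specified).
Leaf segments holding < 5% of cells are pruned iteratively (cells
re-project), which suppresses the spurious side-branches over-clustering
creates along a continuum. Branch points are nodes of degree ≥ 3; a branch
is a maximal branch-point-free segment. This MST-over-centroids tree is a
deliberate, exactly-testable substitute for elastic principal-graph
optimizers (DDRTree and kin): it preserves the decision surface — cluster
labels, pseudotime, branch labels, branch points — not the embedding
aesthetics. The 2D display embedding is t-SNE (seeded, PCA-initialized,
perplexity capped at (n−1)/3) and is display-only.

**Preranked GSEA.** The ranking statistic combines a per-gene p-value with
the sign of the fold change. The default score is sign(FC) × (1 − p): the
literal product sign(FC) × p orders *non-significant* genes to the extremes
of the list, inverting the intended enrichment direction, so the literal
mode is shipped (`mode="literal"`) but not default. Hits advance the
running sum by |score|^w / Σ_hits |score|^w (w = 1), misses retreat by
1/(N − N_hits); ES is the extremum of largest magnitude. The null permutes
set membership (gene labels), seeded; p = (1 + #{|ES_π| ≥ |ES|})/(n_π + 1),
so with 1000 permutations the smallest attainable p is 1/1001 ≈ 0.001. NES
normalizes by the mean |null ES| of the matching sign (asymmetric nulls).
Null ES values are computed from sorted hit positions only (the extremum is
attained adjacent to a hit), which makes 1000 permutations cheap; the tests
verify this fast path against the full running sum. Leading edge: members
at/before the maximum for ES > 0, at/after the minimum for ES < 0.

**Activity scores.** Per-cell gene-set activity is (mean imputed
expression)³ — cubing is monotone on non-negative input, so it reorders
nothing and only sharpens display contrast. "Mean expression cubed" could
also parse as mean(x³); that variant is available as `mode="mean-of-cubes"`.
Pseudotime profiles bin cells by pseudotime quantiles and normalize each
gene's bin means to its maximum (all-zero rows stay 0).

**Regulons.** Inference is out of scope — regulon files are inputs. The
default activity score is the normalized recovery AUC of a factor's targets
within the top 5% of each cell's expression ranking (rank-based, hence
invariant to per-cell monotone transforms); mean-cubed activity is available
for consistency with the gene-set scores. Input genes are pre-filtered
(≥ 10 total counts and expressed in ≥ 9 cells). Activity/expression
coupling between two cell groups uses log₂((mean_a + ε)/(mean_b + ε)) with
ε = 0.01 and Pearson correlation across factors (flagged undefined below 3
factors or zero variance).

## Problem sizes and determinism

The default study conditions — 2000 cells, 1500 genes, 30 spikes, 3 bulk
replicates per label — run the full pipeline in ~10 s on one core; the test
suite simulates at this scale once and reuses it. Every stochastic step
(generator, permutation null, t-SNE) takes an explicit seed; a fixed seed
reproduces byte-identical simulated matrices and identical pipeline
summaries.

## Known limitations

- Branch recovery is measured against generating labels that assign a
  branch from the commitment division onward; cells in the first committed
  divisions are only weakly divergent, so adjusted Rand indices near 0.85,
  not 1.0, are the expected ceiling at default noise.
- Mid-ladder reference labels (divisions 3 and 5) are branch mixtures, so
  division annotation of strongly committed mid-ladder cells degrades
  gracefully (±1 division) rather than exactly.
- The density-peak resolution cap (16 centers) is a resolution choice, not
  an estimate of cluster number; biological interpretation should rest on
  branches and pseudotime, not on the cluster count.
- The dense diffusion operator and full pairwise-distance clustering are
  quadratic in cell number; beyond ~5000 cells both need sparse/approximate
  backends.
- Quantile normalization forces identical per-column distributions; true
  global shifts in expression distribution between modalities are absorbed
  rather than modeled.
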