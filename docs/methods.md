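# Methods

This note documents the models and procedures implemented in `crossneuro`,
the synthetic data the pipeline is validated on, and the numerical choices
made where the design was open. Parameter defaults are collected in
`RunConfig`; all randomness flows from `RunConfig.seed` through a
hierarchical generator (`stage_rng`), one derived stream per stage.

## Synthetic data generator

The generator (`synthetic_data`) emulates a multi-species snRNA-seq study
of cortical neurons with planted, fully recorded ground truth. Counts are
gamma–Poisson (negative binomial): for cell *c*, gene *g*,

    mean_cg = L_c · softmax_g( b_g · 2^{s_cg} ),    x_cg ~ NB(mean_cg, θ)

where `b_g` is a lognormal baseline shared across species and the log2
shift `s_cg` accumulates every planted effect:

* **subtype markers** — each subtype owns a disjoint block of 40 genes at
  log2FC 3 (default). Major GABAergic subclasses in real cortex are
  separated by large, strong marker programs; weaker settings make the
  subtype structure unrecoverable by any method and thus test nothing.
* **inhibitory identity** — *GAD1*/*GAD2* are boosted (+3 log2) in
  inhibitory subtypes and suppressed (−6 log2) elsewhere, mirroring their
  near-silence outside GABAergic neurons; this is what makes marker gating
  meaningful.
* **batch and species divergence** — per-gene lognormal jitter with σ 0.15
  (per batch) and 0.10 (per non-reference species).
* **co-expression modules** — each module shares a standard-normal latent
  factor z per cell, entering as `2^{λ z}` on all module genes (default
  3 modules × 50 genes, λ = 1.0). This is exactly the single-factor
  correlation structure weighted co-expression analysis assumes.
* **regulons** — per-subtype Bernoulli activity masks; active cells gain
  +1 log2FC on all targets (default 18 regulons × 30 targets arranged in
  archetypal activation patterns: conserved-in-all, single-species,
  subtype-restricted, off).
* **disease** — reference-species cells are split control/disease; disease
  cells gain +1 log2FC on the genes of the first module, which doubles as
  the planted risk-gene set.

Module genes and regulon targets draw their baseline from the upper half
of the lognormal (|N(0,1)| in the exponent). Co-expression and rank-based
target recovery are only observable on adequately expressed genes — a
"module" planted on genes with a mean of one count is unrecoverable in
principle, and real module/regulon calls are made on expressed genes.

Library sizes are Gamma with mean 5000; the dispersion default θ = 10
corresponds to a biological CV of ~0.3, the typical extra-Poisson noise
level of UMI-based snRNA-seq. The homology map covers 90% of genes
(one-to-one), always including the *GAD* markers; the remainder exercises
one-to-one filtering. The default design: human + mouse, four conserved
inhibitory subtypes, one excitatory out-group, one mouse-private subtype
(Inc Meis2-like), 200 cells per subtype, two batches per species.

**What the generator does not model:** doublets, ambient RNA, empty
droplets, gene-length effects, many-to-many orthology, cell-cycle or
continuous trajectories, and realistic GEO-scale depth. Passing tests
demonstrate that the statistics recover the structure they are designed
for under their own assumptions — not performance on real tissue.

## Preprocessing and integration

Normalisation is `ln(1 + 10,000 · x / total)` per cell (natural log);
zero-total cells become zero rows with a warning. Variable genes are
ranked by mean-binned standardised dispersion (variance/mean z-scored
within equal-frequency mean bins, ~10 genes per bin minimum; constant
genes always rank last; ties break lexicographically). PCA uses
column-scaled (zero mean, unit variance, |z| clipped at 10) data and a
deterministic sign convention (largest-magnitude loading positive).
Defaults: 3000 variable genes and 50 PCs within species, 2000 and 30 for
the cross-species inhibitory integration.

Anchor correction is a transparent restatement of reciprocal-PCA
integration: both datasets are projected into each other's PCA bases;
anchors are cell pairs that are mutual nearest neighbours (k = 5) in
*both* reciprocal projections; each query cell is shifted by a
Gaussian-kernel-weighted average of anchor displacement vectors. Kernel
weights are computed against anchor *midpoints*, and anchors sharing a
midpoint are aggregated — this makes the correction exactly zero when
query equals reference (the two orientations of every pair cancel).
Deliberately omitted relative to the full Seurat machinery: CCA, anchor
scoring and weight trees.

Clustering builds a shared-nearest-neighbour graph (k = 15, Jaccard
weights) and runs seeded Leiden modularity communities, raising the
resolution by bisection until the community count reaches the target
(default ≥ 31); `method="kmeans"` is a deterministic fallback.

## Conservation scoring

`overlap_score` is the sum over the cluster union of minimum proportions;
off-support clusters contribute zero, so summing over the union equals
summing over shared clusters. It equals 1 − total-variation distance, is
symmetric, and is invariant to cluster relabeling. Inhibitory cells are
gated on any nonzero *GAD1*/*GAD2* normalised expression (no threshold is
stated for this gate in the field; zero is the conservative choice).
Subtype mean-expression correlation uses Pearson (the R `cor` default).

## Neighbour voting

The voting network is Spearman correlation across cells on the gene-set
submatrix, all pairwise values jointly rank-standardised to (0,1]
(average ranks for ties) and symmetrised by averaging with the transpose.
Voting holds out one batch at a time; held-out cells receive the
degree-normalised weighted sum of training labels; AUROC is the
Mann–Whitney U scaled to [0,1] (ties half credit), averaged over batches.
Batches containing a single class are skipped with a warning, not
zero-filled. The supervised wrapper subsamples 20 cells per cluster,
10 iterations, and reports mean ± SD; the SD is exactly 0 when every
cluster has ≤ 20 cells (subsampling is then exhaustive).

## Co-expression modules

Pseudocells average 10 cells within subtype × condition × batch strata —
the conservative reading of per-subtype pooling, which also prevents
condition and batch signal from leaking into one pseudocell. Remainder
groups below 10 cells are dropped; a 25-cell stratum yields exactly 2
pseudocells, a 9-cell stratum none.

The MAD filter defaults to the R-style scaled MAD (×1.4826) at threshold
0.1, with `scaled=False` for the raw variant. The TOM pipeline uses
unsigned adjacency `|cor|^6` by default (a `signed` flag provides
`((1+cor)/2)^6`); with Pearson correlation the bicor-only `maxPOutliers`
concept does not apply. Tree cutting is a static cut of the average-linkage
`1 − ω` dendrogram at height 0.99 followed by the minimum-size filter —
deterministic and testable, in place of the dynamic hybrid cut; the
eigengene merge (first PC of the module's standardised profiles, sign
aligned to the mean profile; iteratively merge pairs with correlation
≥ 1 − 0.25) absorbs most fragmentation the static cut leaves behind.
Modules are named `mod1, mod2, …` by decreasing size.

## Enrichment and differential expression

`hypergeom_upper(k, M, n, N)` is `P(X ≥ k)` for X ~ Hypergeom(N, M, n),
accumulated as a log-space suffix sum over `hypergeom.logpmf` — identical
in meaning to `1 − phyper(k−1, M, N−M, n)` with background N = 20,000.
Star tiers: 0.01–0.05 `*`, 0.001–0.01 `**`, and ≤ 0.001 rendered `***`
(an extension of the two published tiers, recorded here).

DE uses the two-sided Wilcoxon rank-sum (asymptotic, tie-corrected) on
normalised expression. Genes enter testing only if detected in ≥ 25% of
either group and |avg logFC| ≥ 0.25, where avg logFC is the natural log of
(mean de-logged expression + 1) ratios — the Seurat convention. BH
adjustment runs over tested genes. Cross-species stars require adjusted
p < 0.05 *and* |logFC| > 1. DE is computed on normalised (not raw) counts.

## Regulons

Activity is the area under the target-recovery curve within the top 5% of
a cell's expression ranks (ties broken by gene id), normalised so that
targets occupying the very top ranks score exactly 1. Binarisation fits a
two-component Gaussian mixture (10 seeded EM restarts) and thresholds at
the posterior-responsibility crossing nearest the midpoint of the
component means. Two guards handle the realities of AUC score
distributions: a point mass at the minimum (cells recovering no target —
inactive by definition) is excluded before fitting, and a fit whose
component means are closer than 5% of the score range (or whose smaller
weight is below 0.01) falls back to a histogram-valley threshold.
Constant scores mark the regulon inactive everywhere. This construction
is a documented stand-in with the same contract as the published
"bimodal model" binarisation, whose internals are not described.

Species are scored on the shared homologous gene space and each regulon is
binarised once on the merged cross-species score vector — per-species
thresholds are not comparable for the same regulon. Activation fractions
are exact ratios per species-qualified subtype; grouping is k-means
(k-means++ init, 50 restarts, squared Euclidean) with k = 8, groups
relabelled 1..k by descending size. GRN inference and motif pruning are
out of scope; regulons enter as GMT files.

## Problem sizes and determinism

The validation suite runs at desk scale by design: ~1000–1200 cells per
species for conservation and regulons, ~5000 cells / 500 pseudocells for
module recovery, 10 seeds for each stochastic recovery claim. The full
pipeline writes TSV/JSON artifacts with fixed orderings and float
formatting, and a rerun with identical config and seed is byte-identical;
`report/manifest.json` records a content hash per artifact.

## Known limitations

* The anchor correction is a simplification; datasets with strong
  nonlinear batch structure would need the full anchor-scoring machinery.
* The static TOM tree cut can fragment weakly separated modules; the
  eigengene merge compensates only when fragments share a latent factor.
* Mixture-based binarisation degrades when a regulon's score distribution
  is strongly unimodal yet active (e.g. active in ~all cells); activation
  fractions remain informative but per-cell calls are noisier, which caps
  end-to-end (simulation → scoring → grouping) pattern recovery below the
  profile-level ideal.
* Synthetic homology is one-to-one by construction after filtering;
  paralog-rich gene families are not modelled.
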