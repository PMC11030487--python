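# Methods

`pcttools` re-implements, as a tested pipeline, the computational procedures
used to chart the precancer-to-cancer transition in single-cell RNA-seq
atlases: healthy-reference projection of diseased epithelial cells, a
sample-level malignancy index, expression-based CNV scoring, consensus
meta-programs with AUCell activities, and the four-way malignant-transition
(PCT) gene-signature derivation. Because the original multi-study atlas is
not redistributable at desk scale, the package ships a synthetic atlas
generator that plants every statistical structure the estimation stages
exploit, together with the ground truth needed for parameter-recovery
benchmarks. This note records the models, the defaults and why, and what the
synthetic benchmarks do and do not establish about real data.

## Synthetic atlas generator

Counts are gamma-Poisson (negative binomial) draws: for cell *c* and gene
*g*, the mean is

    mu(g,c) = depth_c * p(g,c),   p(g,c) = 2^L(g,c) / sum_g 2^L(g,c)

with log2 mean surface

    L = baseline + marker effects + pseudotime * transition effect
        + sum_p activity_p * loading_p + CNV dosage

and `var = mu + mu^2 / theta` with inverse-dispersion `theta = 10`, a
mid-range value for UMI data. Per-cell depth is Gamma(10, depth/10)
(mean 2,000 UMI, CV ~32%).

Structure planted, and the choices behind it:

- **Stages and malignancy.** Healthy samples have malignancy 0; precancer
  samples draw malignancy from U(0.15, 0.45) and cancers from U(0.7, 1.0).
  The gap mirrors how the transition trajectories behave in real atlases:
  the origin (early lesion) and terminal (carcinoma) states of a trajectory
  differ strongly, which is what makes start-vs-end cluster contrasts
  informative. Per-cell pseudotime = sample malignancy x cell-type
  susceptibility (stem-like cells 1.0, differentiated types 0.5), so
  stem-like cells carry the transition signal.
- **Cell types.** Three epithelial types (STM stem-like, ENT, SEC), 40
  disjoint marker genes each at +2 log2. The stem fraction rises 0.25 ->
  0.4 -> 0.6 across stages.
- **Transition genes.** 60 genes (the default benchmark's "strong" set)
  with +1.5 log2 units of effect at pseudotime 1, planted on a low but
  detectable baseline (uniform −2.0..−1.2 log2 below the gene-baseline
  mean, ~0.2–0.4 expected counts per cell in healthy tissue). The low
  baseline is deliberate: genes that switch from rarely to commonly
  detected are the regime in which fold-change, detection-fraction
  (pct.1 / pct.ratio) and rank-correlation screens can all see the same
  gene; a transition gene planted on an abundantly expressed baseline
  saturates the detection-fraction filter and could never satisfy the
  pct.ratio >= 1.5 rule. Transition genes additionally load (0.5
  log2 per activity unit) on the malignancy-coupled expression program —
  biologically they *are* the genes such programs are made of, and this
  co-expression is what lets the meta-program filter see them.
- **Expression programs.** Three disjoint 40-gene programs with
  half-normal per-cell activities (sd 1.0) and 2.0 log2 loading — active
  cells express program genes ~2–4 fold up, matching the strength of real
  recurrent programs (cell cycle, hypoxia, senescence). Program 0's
  activity is scaled by (0.3 + pseudotime): its prevalence and intensity
  grow along the transition while remaining heterogeneous within each
  sample, so per-sample factorisation can still discover it.
- **CNV.** Two 120-gene segments (chr1 +1, chr3 −1 log2) applied
  multiplicatively to all cancer-stage cells, placed mid-chromosome so a
  100-gene smoothing window can resolve both boundaries.
- **Mitochondrial genes.** 40 `MT-` genes on chrM holding 8% of baseline
  expression.
- **Doublets.** 8% of cells per sample are sums of two same-sample cells
  (heterotypic with probability 0.8), thinned binomially to a typical
  library size; the pre-thinning totals are kept in the ground truth.

Default benchmark size: 3 tissues x 26 samples (10 healthy / 8 precancer /
8 cancer) x 250 cells = 19,500 cells, 2,000 genes. The sample counts are a
deliberate scaled-down compromise: sample-level Wilcoxon tests are discrete,
and with fewer than ~8 samples per side the attainable p-values cannot clear
a BH FDR of 0.05 over 2,000 genes, which would make every pseudo-bulk screen
vacuously empty. Real atlases of this kind have ~100 samples per tissue.

What the generator does **not** emulate: batch effects and ambient RNA,
tissue-specific gene panels, spliced/unspliced layers, spatial structure,
cell-cycle confounding, or transition genes whose effects are non-monotone.
Passing recovery benchmarks therefore shows the estimators are correct and
well-powered under the stated noise model — not that they are robust to
batch confounding or misannotation in real data.

## Quality control and doublets

Cells with fewer than 200 or more than 7,000 detected genes (count >= 1),
or more than 25% mitochondrial counts (`MT-` prefix, case-insensitive),
are removed; the bounds are inclusive for retention since the rule
describes removal strictly beyond them. The expected doublet count per
sample is `round(0.08 * n^2 / 10^4)`; note this quadratic rule
yields 0 for samples under ~250 cells. Because the quadratic formula is
plausibly a transcription of the linear 8%-per-10,000-cell rule (the two agree at
exactly 10,000 cells), the linear form `round(0.08 * n)` is available via
`nexp_rule="linear"`; the recovery benchmark uses it so that the number of
flagged cells matches the planted rate.

Doublet detection is a simplified artificial-doublet kNN procedure:
`pN/(1−pN) * n` artificial doublets (averaged random cell pairs) are
embedded with the real cells by PCA (20 components of log1p CP10K), each
real cell's pANN is the artificial fraction among its `round(pK * n_total)`
nearest neighbours (pN = 0.25, pK = 0.09), and the nExp highest-pANN cells
are flagged, ties broken by barcode. This preserves the pANN mechanism of
the reference doublet detector without reproducing its internals.

## Iterative-LSI reference and projection

Four iterations of: variable-gene selection (top 3,200 by variance of
ln(1+CPM), per cell in iteration 1 and across cluster-mean pseudo-bulk
profiles thereafter; ribosomal RPL/RPS/MRPL/MRPS, mitochondrial MT- and
HLA- genes excluded) -> TF-IDF -> rank-32 randomized SVD -> shared-nearest-
neighbour graph (k = 30, Jaccard edge weights) with Leiden clustering at
resolutions 0.1, 0.2, 0.4, 0.8. The IDF convention is the smoothed
document-frequency form `ln(1 + n_cells / (1 + n_expressing))`, which can
never divide by zero. SVD signs are fixed by making the largest-magnitude
loading of each component positive, so rebuilds are bit-reproducible.

The frozen model keeps the gene list, IDF vector, loadings, singular
values, reference embedding and labels. Projection recomputes only term
frequencies from the query (column sums over the model genes), applies the
stored IDF, zeroes genes that had zero reference row sums, and embeds as
`TFIDF^T U`. The governing contract is the self-projection identity —
projecting the reference through its own model reproduces the stored
embedding to 1e-8 relative error — which pins down the embedding
convention (`V S`, equivalently `TFIDF^T U`). Label transfer takes the
majority label among the 25 nearest reference cells (Euclidean, 32-dim),
ties broken by smaller mean neighbour distance then label order; cells
with no counts over model genes are "unassigned".

## Malignancy index

Per diseased sample, stem-like cells are contrasted with the pooled
healthy stem cells: two-sided Wilcoxon rank-sum per gene (exact null for
small tie-free groups, tie-corrected normal otherwise), BH FDR within
sample, log2FC on de-logged normalised means with pseudocount 1. Axis
genes are those with FDR <= 0.05 and |log2FC| >= 0.5 in at least two
samples. The sample x gene log2FC matrix plus one all-zero "healthy
anchor" row is decomposed by PCA; a principal curve (iterated projection +
lowess smoothing, <= 50 iterations, tolerance 1e-6 on the summed squared
distance) is fitted in the top-2 PC plane, and the index is the normalised
arc length along it, oriented and scaled so the healthy anchor is exactly
0 and the most malignant sample exactly 1. If the log2FC matrix is
numerically rank-1, the curve degenerates to a PC1 ranking (logged).
Healthy samples all sit at the anchor. One axis is fitted per tissue.

Downstream: per-gene expression dynamics along the index use a tricube
local-linear smoother (bandwidth 0.5 in index units, 100-point grid);
cell-type composition trends are Spearman correlations of per-sample
fractions against the index, BH-corrected across types.

## CNV profiles and score

Gene-wise relative expression (log-normalised minus the healthy-reference
mean) is clipped to ±3, averaged over a centred 100-gene moving window
within each chromosome (truncated at ends; chromosomes with fewer than 100
genes are dropped), and re-centred per cell by its median smoothed value.
The per-cell CNV score is the mean of squared smoothed values across all
retained genes. The window, clip and re-centring follow the canonical
expression-CNV estimation recipe and are config-exposed. The CNV
normalisation input is ln(1 + CPM/10).

## Meta-programs and AUCell

Per diseased sample, stem-cell expression (log-normalised, per-gene
centred, negatives clipped to zero, restricted to the 1,500 most variable
genes) is factorised by multiplicative-update NMF (Frobenius objective,
500 iterations or relative-error change < 1e-5) at ranks 4–9 plus one
anchor fit at rank 3; the optimal rank maximises the second difference of
the reconstruction error (the anchor makes an elbow at the smallest
candidate rank visible). Each factor is summarised by its 50 top-loading
genes.

Consensus: programs are first filtered for robustness — a program must
share at least 10 of its top genes with a program from a different sample
(random 50-gene factors from a ~1,500-gene pool share ~2 by chance), which
removes sample-specific noise factors. Genes appearing in >= 2 robust
programs are embedded as binary program-membership vectors and clustered
by K-means (k in 2–7 chosen by maximal silhouette, 20 restarts, fixed
seed); each cluster is a meta-program, and each program is assigned to the
module sharing the most genes. Recurrent detection-noise genes typically
form one large incoherent module — the analogue of the "unknown" modules
dropped during manual annotation; a user-supplied blocklist can remove
such modules, and no automatic annotation is attempted. Pairwise module
overlaps are scored by the upper-tail hypergeometric test.

AUCell activity: per cell, genes are ranked by descending expression (ties
broken by one seeded random gene permutation), and the score is the area
under the gene-set recovery curve within the top 5% of ranks, normalised
by the maximal possible area; it is 1 when the set occupies the top ranks
and 0 when it is entirely below the threshold. Meta-program-vs-covariate
associations use Spearman correlation with the signed R >= 0.7 flag rule.

## PCT signatures

Four candidate screens per tissue, at the procedure's canonical thresholds:

1. **Pseudo-bulk DEGs** — per-sample mean de-logged expression over stem
   cells; Wilcoxon across samples (diseased vs healthy), BH FDR < 0.05 and
   log2FC > 0.25 (strict).
2. **Subcluster DEGs** — between trajectory core clusters, kept when
   avg_log2FC >= 0.25, pct.1 >= 0.25 and pct.ratio >= 1.5 in >= 1 pair.
   The pipeline defines the core clusters as the bottom and top quartiles
   of the input per-cell pseudotime (the trajectory's origin and terminal
   states); pseudotime itself is an accepted input column, since velocity
   and graph-learning inference are outside this package's scope.
3. **Transition genes** — Spearman of expression vs pseudotime across
   diseased stem cells, BH FDR < 0.05.
4. **Meta-program genes** — Spearman of expression vs the meta-program's
   AUCell activity, BH FDR < 0.05.

The four sets are intersected within each tissue and unioned across
tissues; each candidate gene is scored by the geometric mean over its
contributing tissues of max(rho, 0), where rho is the pseudotime Spearman
coefficient (a config switch pools the meta-program rho as well).
Geometric means of signed coefficients are undefined, so non-positive
coefficients clip to zero, and a zero in any contributing tissue zeroes the
gene's score and drops it. The 100 top-ranked genes (ties by name) form
the signature for that meta-program.

## Numerical and reproducibility choices

- All randomness flows from one top-level seed via fixed per-stage
  substreams; reruns produce byte-identical outputs and manifests
  (SHA-256 per stage output file).
- Wilcoxon p-values use the exact null automatically for small tie-free
  groups, matching enumeration oracles for group sizes <= 8; rows constant
  across both groups report p = 1.
- BH adjustment passes NaNs through (undefined correlations are reported
  as NA, never silently dropped into the family).
- Spearman screens use the rank-transform + t-approximation, identical to
  the reference implementation's default.
- Degenerate inputs: all-zero cells are flagged, not errors; empty gene
  sets score 0 with a warning; single-class AUROC and constant covariates
  report NA; an empty four-way intersection yields an empty signature with
  a warning.

## Benchmark problem sizes

Unit tests use one-tissue atlases of 1,500–6,500 cells; the recovery
benchmarks use 30 samples (malignancy index; seeds 1–5), ~3,000 healthy
cells (self-projection, label transfer), the default 19,500-cell atlas
(end-to-end, CNV) and a 3-tissue / 800-transition-gene atlas for the
signature-truncation check. These sizes were chosen as the smallest at
which the sample-level statistics have honest power, and they keep the
full suite and the acceptance script each within tens of minutes on one
CPU.

## Known limitations

- The simplified doublet detector shares the pANN mechanism but not the
  parameter sweep of the reference tool; its quadratic nExp rule flags
  nothing for samples under ~250 cells.
- The principal curve is fitted in 2 PCs with a PC1 fallback; strongly
  non-planar sample manifolds would need more components.
- Meta-program discovery assumes programs are heterogeneous *within*
  samples; a program uniformly active in every cell of a sample is
  invisible to per-sample factorisation.
- The malignancy index is relative per tissue; positions are not
  comparable across tissues beyond rank order.
- Subcluster core-cluster definition relies on a supplied pseudotime; with
  no pseudotime column the subcluster screen cannot run.
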