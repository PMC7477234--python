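# Methods

This note documents the models, numerical choices, and deliberate design
decisions behind `hypomod`, in the order the pipeline runs.

## Synthetic data model

Counts are negative binomial with the mean–dispersion parameterization
`Var(y) = μ + α μ²`. Per-gene dispersions α are drawn from a gamma prior
(shape 2, scale 0.15 by default, giving a typical α ≈ 0.3, in the range
seen for UMI pseudobulk data). Gene-level parameters — baseline relative
abundance (log-normal) and dispersion — are derived from the config seed
alone, so independently seeded draws from one config (for example a
reference atlas and a query dataset) describe the *same genes* and differ
only in cells. Cell-level structure enters the log2 mean additively:

- **markers**: genes assigned to a cell type gain `marker_log2fc`
  (default 2) in that type;
- **planted DE**: a configured fraction of unassigned genes shift by a
  random ±log2 FC in treated cells of the affected types;
- **modules**: member genes share a per-cell latent Gaussian factor
  `f_c ~ N(μ_group, 1)` scaled by a loading; treatment shifts the factor
  mean, so the module eigengene has a known treatment effect;
- **gradient**: cells of one type carry a latent position `t ~ U(0,1)` and
  zone markers follow smooth user-supplied log2 mean functions of `t`.

Per-cell depth is log-normal (meanlog 8 ≈ 3000 UMIs, sdlog 0.3, near the
reported per-cell recovery of the study's single-nucleus data); gene means
are renormalized to proportions per cell so a cell's expected total equals
its drawn depth. Mitochondrial and ribosomal genes are flagged trailing
genes whose aggregate abundance is scaled to the configured expected
shares, so QC fraction filters are exercisable. The default design is 3
treated + 3 control samples (the Day-1 cohort size); the Day-5 design
(6/group) is a config change. Doublets and ambient RNA are not simulated —
passing tests say nothing about doublet robustness.

## QC and clustering

Filters run cells-then-genes in a fixed order with the boundary semantics
of the stated thresholds: keep cells with detected genes in [400, 4000]
and combined mito+ribo UMI share ≤ 20% (single-cell) or ≤ 5%
(single-nucleus), then drop genes detected in fewer than 10 (or 5) cells.
The mito/ribo share is thresholded on the *sum* by default (the two can be
split with `separate_mito_ribo=True`); the conjunction is ambiguous in the
source protocol and the sum is the stricter reading. Normalization is
log1p of depth-scaled counts (scale 1e4) — a fully specified substitute
for variance-stabilizing transforms, since downstream statistics consume
only a normalized matrix; unwanted covariates (total UMIs, mito/ribo
fraction) are regressed out per gene by OLS at the scaling step, residuals
are unit-scaled and clipped at ±10. Genes fully explained by covariates
(residual sd < 1e-10) keep their zero residuals rather than amplifying
numerical noise.

PCA is an exact SVD with a deterministic sign convention (largest-magnitude
loading positive). Clustering builds a kNN graph (k = 20) with
shared-neighbor Jaccard weights and partitions it with seeded Leiden
modularity optimization at resolution 0.1; cluster ids are dense integers
ordered by size. Cells with silhouette < 0 in PC space are removed
(singleton clusters score 0 and are kept), and clusters in which any
single sample contributes ≥ 50% of cells are flagged — the boundary is
inclusive, a logged choice where the protocol wording is non-strict.

## Label projection

Anchor-based transfer is replaced by a fully specified projector: variable
genes, scaling parameters, and PC loadings are fit on the labeled
reference; query cells are normalized, scaled with the *reference* means
and sds, projected onto the reference PCs, and labeled by majority vote
among the k = 30 nearest reference cells. Confidence is the vote fraction
(multiples of 1/k); ties break by smaller mean neighbor distance, then
lexicographically. Two guards matter in practice:

- a query cell whose mean neighbor distance exceeds the 99th percentile of
  the reference's own mean kNN distances is left unassigned: vote
  fractions carry no distance information, and without this guard query
  types absent from a reference are unanimously mislabeled;
- a reference sharing fewer than 10 genes with the query degrades to a
  warning and no assignments.

Iterative projection applies references in order, removing confidently
labeled cells between rounds; swapping reference order can change
assignments, so per-reference counts are reported.

## Pseudobulk differential expression

Counts are summed per gene per sample over the masked cells; samples are
the unit of replication. Size factors are median-of-ratios rescaled to
geometric mean 1 (library-size fallback when no gene is positive
everywhere). Dispersion is method-of-moments on size-factor-normalized
counts, pooled within groups and floored at 1e-8; there is deliberately no
shrinkage, which keeps the engine self-contained and testable. The GLM is
a log-link NB fit by IRLS, vectorized across genes, with offset
log(size factor) and a fixed-effect batch column when more than one batch
is present. The Wald statistic for the treatment coefficient is referred
to **t(n_samples − n_coefficients)** rather than the normal: without
dispersion shrinkage the normal reference is anticonservative at 2–6
samples per arm, while the t reference keeps the empirical type-I rate at
α = 0.05 within [0.03, 0.08] on 3 vs 3 null simulations (verified in the
test suite). Genes with all-zero counts are reported as category `low`
with missing p. BH-FDR is applied across tested genes; volcano categories
use configurable |log2 FC| and FDR cutoffs (0.25/0.05 by default, 0.5 or
1.0 elsewhere in the source analyses — they are parameters, not
constants).

The downsampling test draws, per iteration, 10 cells per cluster per
sample without replacement, re-runs the pseudobulk test, and counts genes
at FDR < 0.1; 100 iterations give a per-cluster DEG-count distribution
summarized by median and IQR. Clusters lacking 10 cells in at least two
samples per arm are skipped and logged, never sampled with replacement.
Gene-level correction within an iteration is BH (matching the FDR
thresholds the results quote); Bonferroni is reserved for across-cluster
comparisons, and both are reported where relevant.

## Co-expression modules

The network is signed: `a_ij = ((1 + cor_ij)/2)^β`. The soft power β is
the lowest candidate in 1..30 whose scale-free fit R² reaches 0.8, after
discarding candidates whose mean connectivity sits at or above the 95th
percentile of candidate mean connectivities (one defensible reading of an
ambiguous discard rule; the report carries the full sweep so other
readings can be audited). The fit regresses log10 p(k) on log10 k over 10
equal-width connectivity bins — equal-occupancy bins would make p(k)
constant by construction — and only negative-slope fits count. On pure
noise the statistic can still reach 0.8, but only at high powers (>12);
structured data qualify at low powers (3–8 in the test fixtures).

TOM follows `TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij)`
and 1 − TOM is the clustering distance (average linkage below 3000 genes,
complete above). Dynamic hybrid tree cutting is replaced by a
deterministic **largest-gap cut**: a branch is cut at the midpoint of the
largest gap in its sorted merge heights when that gap exceeds a fraction
of the branch's height range (0.25 for deepSplit 2, 0.15 for deepSplit 4 —
the smaller fraction splits on smaller gaps, so the deepSplit-4 partition
refines the deepSplit-2 one by construction), a cut is accepted only if it
carves out at least two clusters of the minimum size (15 genes), and
accepted branches are re-cut recursively. Branches with a height
continuum — the signature of one correlated block — are emitted whole;
noise genes shatter below the gap and grey out. There is no post-hoc
reassignment (the pamStage-off analogue). The gap rule is conservative: at
some seeds a marginal gap (relative size just below the threshold) leaves
blocks merged rather than inventing spurious splits.

Module eigengenes are unit-norm first-PC cell embeddings of the
standardized member submatrix, oriented to correlate positively with mean
member expression. Merging is iterative: while any eigengene pair has
dissimilarity 1 − r ≤ 0.2 (correlation ≥ 0.8; the boundary is inclusive
with a 1e-9 tolerance against floating-point noise), the closest pair is
merged and eigengenes recomputed. kME is the gene–eigengene Pearson
correlation.

Module–treatment association fits, per module, a Gaussian linear mixed
model on the per-cell eigengene with a random intercept per sample and
treatment (plus batch) as fixed effects. The fit is REML with the single
variance ratio profiled in 1-D; the per-sample covariance
`I + λ 11ᵀ` is inverted in closed form, so the fit is fast and never
fails to converge. The Wald statistic is referred to
t(n_samples − n_fixed) — the between-sample information that identifies a
treatment effect — which is exact for balanced designs and keeps null
p-values uniform at 2–6 samples per arm (a normal reference does not;
verified by sample-permutation calibration in the tests). A boundary fit
(λ = 0) degenerates to OLS point estimates with the same conservative df
and is warned about. Observations are per cell, consistent with eigengenes
being cell embeddings; p-values are BH-corrected across modules.

## Pseudoventricle

The principal curve is the Hastie–Stuetzle alternation: initialize lambda
at the first principal component, then repeat {order cells by lambda;
smooth each coordinate against lambda with a lowess smoother, span 0.3 of
the lambda range; re-project cells onto the resulting polyline} until the
total squared projection distance changes by < 0.1% (tol 1e-3) or 50
iterations. Lambda is the arc length of the projection foot. Orientation
flips lambda so the ventral-anchor-high end maps to 0 (anchors correlating
|r| < 0.1 with lambda warn and keep orientation), then rescales linearly
to [0, 30]: the absolute scale behind a "width-1" bin is not recoverable
from the source text, so 30 bins is the figure-consistent default and
`n_bins` is a parameter.

Scaled module expression is the mean z-score of member genes
(zero-variance genes contribute 0). Each width-1 bin with ≥3 cells and ≥2
samples per group is tested with the same random-intercept mixed model
(falling back to a Welch t test when an arm retains one sample — logged);
Bonferroni correction spans tested bins only, untested bins break
consecutive runs, and a module flags as spatially responsive at ≥5
consecutive significant bins.

## Enrichment

Hypergeometric over-representation intersects terms with the declared
background, tests only terms of 10–300 background genes overlapping the
query in ≥3 genes, and Bonferroni-corrects over the tested terms. The
direction z-score is `(n_up − n_down)/√n_overlap`, with genes in neither
direction set counting only in the denominator; an empty overlap is
undefined. Hierarchical GO filtering and ordered-query scoring of the
original web service are not reproduced; ordered queries are approximated
by running nested top-k prefixes when needed. Preranked GSEA uses the
weighted KS running sum (hit increments ∝ |stat|^1), a gene-label
permutation null, NES = ES / mean |same-sign null ES|, and an add-one
two-sided empirical p (floor 1/(n_perm+1)). RRHO is the one-sided
over-enrichment map over top-list threshold pairs; it calls the same
hypergeometric kernel as the enrichment path, which the tests pin to
1e-12 agreement, with an optional Benjamini–Yekutieli-adjusted grid.
Reactivity genesets take per-condition DE tables (log2 FC > 2, FDR < 0.05,
the FDR clause droppable per table), move genes shared by the designated
pair into a PAN set, and strip remaining cross-pair overlaps so the
condition-specific sets are disjoint.

## Orchestration and reproducibility

The pipeline runner executes a validated stage list (unknown keys and
stages are rejected with suggestions), writes TSVs with full float
precision, and appends a manifest entry per stage (parameters, derived
seed, output hashes, shapes). One global seed fans out as
`SeedSequence([seed, stage_index])`, so re-running a stage never depends
on earlier stages' draws. The subcommand surface is deliberately thin
(`run`, `validate-config`); the library functions are the primary
interface for per-stage work.

## Problem sizes in the test suite

The suite runs simulations at desk scale, chosen to keep each calibration
statistically meaningful: 500 null genes at 3 vs 3 for DE type-I, 100
downsampling iterations over ~1000 cells, 200 sample-permutation
replicates for mixed-model uniformity, 20 seeded replicates of the full
module chain (300 genes × 480 cells), and 1000-cell trajectory fits. The
headline cell counts of the motivating study (tens of thousands of cells)
exceed what property tests need; all thresholds above are independent of
scale.

## Known limitations

- The vote-fraction confidence is not the anchor-based prediction score it
  replaces; the 0.75/0.50 thresholds are kept as interface constants, not
  calibrated equivalences.
- No dispersion shrinkage means single-gene fold-change estimates are
  noisier than shrinkage-based engines at very low counts; calibration,
  not per-gene agreement with any external tool, is the design target.
- The largest-gap cut recovers well-separated modules exactly but can
  leave marginally separated blocks merged (conservative) where the hybrid
  tree cut might split them.
- Doublet detection, anchor-based batch integration, and pseudotime
  methods beyond the principal curve are out of scope; batch is handled as
  a fixed effect throughout.
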