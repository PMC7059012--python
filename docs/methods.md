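# Methods

`amyglia` re-implements, as a tested pipeline, the analysis chain used to ask
whether Alzheimer's-disease (AD) GWAS risk genes converge on an
amyloid-responsive, microglia-dominated co-expression module.  The study
design it models is a two-strain mouse cohort — an amyloid model ("APP") and
a tau model ("TAU") — each with a 2 × 2 age × genotype layout
({4M, 10M} × {WT, TG}, n = 12 per cell), plus a companion single-microglia
UMI experiment.  All stages run on synthetic data with recorded ground
truth, so every claim the pipeline makes can be checked against a known
answer.

## Bulk differential expression

Counts are filtered (a gene is kept when its raw count exceeds `min_mean`
= 5 in at least `min_samples` samples, the fraction 10/96 of the cohort by
default), log2-CPM transformed with pseudocount 0.5, and residualized
against technical covariates (library-prep batch, RNA concentration) by a
joint least-squares fit in which the biological design is protected — the
same semantics as limma's `removeBatchEffect`.  Per gene, ordinary least
squares on the four (genotype, age) cell means yields three contrasts:

- `age`: mean(10M) − mean(4M);
- `genotype`: mean(TG) − mean(WT);
- `age_x_genotype`: by default the aged-transgenic cell versus the mean of
  the other three cells (`vs_rest` style — what moves only in aged TG
  animals); the classical difference-in-differences is available as
  `contrast_style: classical`.  Reference analyses of this design are
  ambiguous about which estimator their interaction fold changes use, so
  both are first-class here and neither is privileged.

P-values are two-sided t-tests on the contrast (residual df = n − 4);
multiplicity uses Benjamini–Yekutieli (BY), valid under the arbitrary
dependence of overlapping contrasts.  We use plain OLS rather than voom
precision weights with empirical-Bayes moderation: moderation parameters
are rarely reported for fits of this design, and at n = 12 per cell the moderation
mainly affects borderline genes; moderation remains an extension hook.
Zero p-values are floored at 1e-300 before the signed log10-p ranking
metric sign(LFC)·(−log10 p).  Cross-strain agreement is Spearman's rho on
the metrics of genes BY-significant in either strain, with a Fisher-z 95%
CI; ties get average ranks and the t approximation.

## Preranked gene-set enrichment

Nested risk-gene sets are thresholds on a per-gene association p-value
(`P_mar`), restricted to the expression universe.  Enrichment in a ranked
list uses the weighted Kolmogorov–Smirnov running sum (weight exponent
p = 1; hits increment by |metric|^p normalized over set members, misses by
1/(N − N_hits); the ES is the extremum of the running sum).  Set genes
absent from the ranking are dropped; an all-zero-weight set falls back to
uniform increments with a warning.  The null is gene-set resampling
(default 1,000 draws); p is the add-one same-sign tail
(1 + #{|ES₀| ≥ |ES|, same sign})/(1 + #same sign), and NES divides ES by
the mean |ES₀| of that sign.  Resampling resolution bounds p at
1/(n_resamples + 1); analytic tail approximations are deliberately not
attempted.  Discrete overlaps (module × marker set, module × risk set) use
the one-sided hypergeometric upper tail with a log2 odds ratio (Haldane
0.5 only when a 2 × 2 cell is zero) and joint BY adjustment per family.

## Co-expression modules

Unsigned weighted network per strain: adjacency |cor|^β with β the smallest
candidate whose connectivity distribution satisfies an approximate
scale-free fit (signed R² ≥ 0.9 on a log–log regression over 10 equal-count
connectivity bins; if no candidate reaches the target the best-fitting power
is used with a warning).  Topological overlap is
TOM_ij = (l_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij) with a_ii = 0 and
TOM_ii = 1.  Modules come from average-linkage clustering of 1 − TOM with a
static absolute cut at height 0.95, a minimum size of 30, and iterative
merging of modules whose eigengenes correlate (absolutely) above 0.75.

The cut rule is the one genuinely open design point.  Dynamic tree cutting
(`cutreeHybrid`) is intentionally not reproduced: the biological claims
this pipeline supports depend on module recovery, not on the cut heuristic.
A cut at a *quantile of merge heights* fails structurally on data whose
background is uncorrelated — noise merges pile up at heights ≈ 0.99 and any
height quantile absorbs planted modules into the background blob.  An
absolute cut on the 1 − TOM scale separates them cleanly: co-expressed
subtrees complete well below 0.95 while pure-noise merges sit above it.
Module counts are cut-dependent and are not a supported output; module
*recovery* is.  Eigengenes are the first principal component of the
gene-standardized submatrix, oriented positively against the module mean
profile (ties break toward the lexicographically first gene).

## Exact multi-set intersection

For k sets of sizes n₁…n_k drawn uniformly from N background genes, the
intersection size follows an exact law computed by iterated hypergeometric
convolution in log space (the running intersection of j sets of size m
meets set j+1 as Hypergeometric(N, m, n_{j+1})).  The expectation is
N·∏(nᵢ/N); the reported p is the one-sided upper tail.  Log-space
arithmetic keeps tails of order 1e-11 exact at N ≈ 16,000.  At
reference-scale inputs — sets of 314, 798 and 4,236 genes over a
15,824-gene background — the expectation is ≈ 4.24 genes; all inputs are
exposed explicitly and no external value is hard-coded.

## Cell-type composition shifts

Expression is z-normalized against the young wild-type baseline:
Z_is = (E_is − mean over baseline samples)/(sd over all samples); constant
genes are excluded with a warning.  The statistic Z_tg is the mean of Z_is
over a marker set × group.  The null resamples random same-size gene sets
from the full universe (10,000 by default; the same draws are reused across
groups for a set size — the draws are group-independent, and reuse removes
between-group Monte-Carlo variance), fits a Gaussian (normality is checked
with D'Agostino's test at α = 0.01 and recorded per result), and reads p
from the normal CDF — two-sided by default since both directions of shift
are of interest; one-sided is a flag.  Bonferroni multiplies by
(#non-baseline groups) × (#sets) computed from the actual call.

## Single-microglia processing

QC removes cells with < 750 reads, > 5% mitochondrial reads, or totals
above a doublet cap of 30,000 — the cap is applied to **total counts**
(a per-cell cap of 30,000 *distinct genes* could never trigger in a
smaller gene universe, so counts is the only workable unit; the threshold
and its unit are configurable).  Each failed
cell records one primary reason (reads → mito → doublet).  Genes detected
in < 100 surviving cells are dropped.  Normalization is
ln(1 + 10⁴·umi/total).  State signatures (homeostatic HM versus activated
ARM) are scored per cell as mean signature expression minus the mean over
expression-matched random controls (24 equal-count bins over mean
expression, 100 controls per signature gene, drawn outside the signature —
a stricter control population than including signature genes in the pool).
Cells take the argmax state (lexicographic tie-break); graph clustering and
anchor-based integration are deliberately replaced by this signature
argmax, because the downstream quantities (state fractions, ARM-vs-HM DE)
depend on labels, not on a clustering algorithm.  ARM-vs-HM differential
expression is a two-sided Wilcoxon rank-sum with Bonferroni correction;
the fold change is the natural log of (mean expm1 + 1) ratios, matching
the convention of the |0.2| significance threshold (strict inequality).

## Microgliosis-aware deconvolution

A microgliosis index M_g is the mean microglial-marker z per group,
anchored additively so the lowest group sits at 1 (z means can be negative,
so a ratio is ill-defined; the divisive convention is available behind a
flag).  The prediction for a gene is
P_g = M_g·(f_HM·μ_HM + f_ARM⁺·μ_ARM⁺), with fractions from the single-cell
state assignment and state means from the normalized single-cell matrix
(ARM⁺ = all non-homeostatic cells; missing compartments contribute 0 with
a warning).  Observed group means are regressed on P_g with an intercept
(bulk contains non-microglial background signal); a gene counts as
"explained by microglia" when r² ≥ 0.67 and the BY-adjusted slope p is
significant.  Regressing observed on predicted versus the reverse is a free choice
here; r² is identical either way, and observed-on-predicted is used.  A first-order (Sobol-style) variance decomposition —
varying one factor with the other held at its mean — attributes predicted
variation to microgliosis versus state-fraction change; this decomposition is an
addition of this package.

## Synthetic data: what it emulates, and what it does not

Bulk counts are negative binomial (variance μ + αμ², single α = 0.1) with
log-normal gene abundances (σ = 1.2) over 2,000 genes and ~10⁶ reads per
sample (real cohorts of this design average several-fold more; ~10⁶ keeps
desk runs fast and leaves per-gene counts in the hundreds).  An amyloid program of 150 genes
carries the interaction effect (log2 LFC 2.0) only in the amyloid strain's
TG-10M cell, plus a per-sample activity factor (log2-normal, σ = 0.3)
confined to the amyloid strain — the program is the amyloid response, and
the activity factor is what gives module detection within-group correlation
to work with.  Seven disjoint cell-type marker sets (120 genes each at desk
scale; the reference panel sizes 701/364/239/435/452/352/483 are available
by config) are planted; microglial markers scale with a per-group
microgliosis factor (1.5 and 3.0 in amyloid TG at 4M/10M, 1.1 in tau TG at
10M — the tau response is mild, matching the qualitative biology that tau
pathology provokes little risk-gene or microglial program response), and
neuronal markers are depressed in tau TG groups (0.85/0.7).  A quarter of
the program overlaps the microglial marker set.  Program and marker genes
are drawn from a low-abundance band (log-space [−3, −1.5]): minority-cell
markers are low-abundance in bulk, and this keeps the planted fold changes
a sub-percent share of the library so that CPM normalization does not
induce a compositional shift on unrelated genes.  Technical structure is a
multiplicative batch factor on library size (which CPM cancels by design —
residualization is exercised on dedicated fixtures with gene-level batch
offsets) and a scalar concentration covariate.

Risk genes (300 by default) place a configurable fraction
(`enrichment_strength`, default 0.6) inside the program with log-uniform
`P_mar` in [1e-8, 5e-2); the rest land uniformly with uniform p in
[5e-2, 1].  Single-cell data draws per-cell states from the per-group ARM
fractions (26.5% → 56.7% across age in amyloid TG, 14.9% → 21.3% in tau TG,
4–10% in WT), then multinomial UMIs from state-specific profiles (ARM/HM
signatures of 50 genes at ±2 log2 units), depths log-normal around 2,500,
and a designated 5% mitochondrial gene slice whose per-cell share varies so
the 5% QC rule has work to do.

Not emulated: read-level artifacts (UMI collisions, ambient RNA,
cross-species spike-in demixing), outlier animals, batch-specific
gene-level effects in bulk, shared aging programs across the two strains
(so cross-strain rank correlations on synthetic data are null, unlike the
strong aging concordance real cohorts show), more than two microglial
states, and any correlation between a gene's bulk abundance and its
single-cell profile beyond what the deconvolution fixtures construct
explicitly.  Passing
tests therefore demonstrate that the statistics recover the structures
they target at realistic noise levels — not that they would survive every
failure mode of real sequencing data.

## Problem sizes and numerical choices

Default analysis runs use 2,000 genes × 96 samples, 800 cells × 8 groups,
1,000 enrichment resamples and 10,000 shift resamples.  Calibration checks
average over 20 generator seeds; the shift-test calibration uses 2,000
resamples per seed (the Gaussian fit is stable well below 10,000) and the
end-to-end scenario check uses 20 seeds of the full pipeline.  All
randomness descends from one master seed through named child generators,
so every table is bit-reproducible; identical configs yield identical
report hashes.  Degenerate inputs fail loudly: empty design cells, aliased
covariates, zero library sizes, covering gene sets, zero-spread resampling
nulls and out-of-support intersection counts all raise typed errors, while
recoverable oddities (constant genes, empty control bins, zero p-values)
warn and continue.

## Known limitations

- Plain OLS is slightly liberal relative to moderated t at very small n;
  the type-I criterion (5% ± 1%) is met at n = 12 but would not be at n = 3.
- The GSEA-style gene-set resampling null assumes exchangeable genes; for
  strongly co-expressed sets the p-values are anti-conservative, which is
  inherent to preranked mode with set resampling.
- The static module cut trades the adaptivity of dynamic tree cutting for
  determinism and transparency; on data whose modules complete above the
  cut height it will under-split.
- The deconvolution regression has only as many points as groups (8 in the
  two-strain layout); r² at such sizes is noisy, which is why verdicts
  combine r² with a BY-adjusted slope p.
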