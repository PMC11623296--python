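# Methods

## Distances and ratios

Expression vectors are compared after log2 transformation and z-score
standardization.  On linear-scale data a pseudocount of 1 is added
before the log (`log2(x + 1)`); data declared `log_space` skip both the
pseudocount and the log.  Standardization uses the sample standard
deviation (n − 1 denominator), which gives the exact identity

    TD²(x, y) = 2 (n − 1) (1 − r)

between the squared Euclidean transcriptomic distance and the Pearson
correlation r of the two log vectors — used throughout the test suite
as an independent oracle.

Three distance measures are available.  `euclidean` is the primary one;
`spearman` is defined as 1 − ρ computed on the raw (pre-standardization)
log values, and `cosine` as 1 − cosine similarity of the standardized
vectors.  The correlation-based forms are this package's conventions
for a "correlation distance"; they are monotone substitutes, not
re-derivations of any external definition.

The TD ratio is TD(X, OT)/TD(X, TT).  Zero denominators return a
flagged `inf` sentinel rather than raising, so cohort aggregation can
drop degenerate samples with a logged count; when both distances are
zero the ratio is defined as 1 (the sample sits on both references,
which can only happen when the references z-score identically).

## Reference profiles

A tissue's reference is the per-gene median of its normal samples.  For
sparse single-cell data the mean is preferred (`statistic="mean"`),
because medians over zero-inflated counts collapse to zero for most
genes.  References are built after normalization, on the same scale as
the cohort matrix.

## Normalization

`normalize_counts` supports CPM, upper-quartile (each sample divided by
its 75th-percentile value, linear-interpolation quantile), and TMM-CPM.
TMM is implemented from the published trimmed-mean-of-M-values
definition: reference sample = the one whose upper-quartile fraction is
closest to the mean, 30% two-sided trim on M-values, 5% on A-values,
inverse-variance precision weights, factors renormalized to geometric
mean 1; CPM is then computed on effective library sizes.  The
implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
printed precision on heterogeneous fixtures (frozen in the test suite).

## Pathway-level analysis

Groups are (cancer type, primary/metastatic class, target tissue) cells
with at least 3 samples.  A pathway enters the analysis if at least 90%
of its genes are present in the harmonized gene list (70% recommended
for sparse single-cell data).  The pathway-specific value is the group
median of per-sample TD ratios (or PMT scores) computed on the
pathway's genes only — standardization is re-done within the gene
subset.  The delta is that median divided by the group's all-genes
median, so delta = 1 exactly when the pathway is the whole gene list.

Empirical significance: for each (group, pathway-size) pair, `n_iter`
(default 10,000) random same-size gene sets are drawn from the analyzed
genes and their deltas form the null.  P = (r + 1)/(n + 1) with r the
number of null deltas ≥ the observed one; the two-sided fold
min(P, 1 − P) makes both tails (pathway closer to TT, or closer to OT,
than random genes) significant.  Nulls are cached per size and re-used
across pathways of the same size within a group — draws of a given size
are exchangeable, so the re-use is mathematically exact, and each group
gets an independent seeded stream.  BH FDR runs across all rows of one
invocation (the FDR family is the full output table, recorded in the
output), with a significance threshold of 0.1.

## Specificity and purity

The specificity analysis fixes the OT, swaps every candidate tissue in
as the TT of the normalized ratio TD(OT, TT)/TD(X, TT) (the numerator
is constant across samples, making candidates comparable), and tests
true-TT > candidate per decoy with one-sided signed-rank tests paired
by sample, BH-corrected.  A candidate identical to the true TT yields
all-zero differences; this is scored p = 1 and never counted.

Purity handling follows a two-step rule: the Spearman test between
ratio and purity runs separately in the primary and metastatic classes;
if either is significant at p < 0.05 the dataset's ratios are replaced
by OLS residuals of `ratio ~ purity` fitted once on the pooled samples.
Pooling the fit (while testing per class) keeps primary and metastatic
residuals on a common scale for the downstream paired comparison; this
was a genuinely open design point and is the package's choice.
Residualization is idempotent and leaves residuals with mean 0.

## Enrichment

Genes are ranked by log2(geometric mean metastatic / geometric mean
primary) on linear-scale values, with a pseudocount of 1 added before
the geometric mean so zero counts are tolerated.  The enrichment score
is the classic weighted Kolmogorov–Smirnov running sum (hit increments
∝ |score|^1, miss decrements uniform; the ES is the largest-magnitude
excursion).  The null is gene-permutation: random same-size sets on the
same ranking.  The p-value is computed against the same-sign portion of
the null — the ES null is bimodal, and ignoring the sign split makes
p-values anti-conservative.  NES = ES / mean |null ES| of the same
sign.  This plain permutation scheme approximates, but does not claim
equivalence with, adaptive multilevel p-value estimators.

For unpaired cohorts, per-sample pathway activity is a rank-ECDF
(ssGSEA-style) score: within each sample, the difference between the
weighted in-set ECDF (weights rank^τ, τ = 0.25) and the uniform
out-of-set ECDF is integrated along the ranking and normalized by the
gene count.  A kernel-density variant of per-sample enrichment is
deliberately not re-implemented: downstream the scores enter only
between-group rank-sum tests, which depend on the scores solely through
their within-cohort ordering, and the rank-ECDF score is a monotone,
transform-invariant statistic of the same ranking.  Ties in expression
are broken by stable gene order.

## Statistical tests

Paired comparisons use the Wilcoxon signed-rank test with zero
differences dropped (logged).  For n ≤ 25 and tie-free magnitudes the
p-value comes from the exact distribution over all 2^n sign
assignments; ties or larger n fall back to midranks with a
continuity-corrected normal approximation.  Unpaired comparisons use
the Wilcoxon rank-sum test, exact for tie-free groups with
min(n₁, n₂) ≤ 10.  Multiplicity control is Benjamini–Hochberg step-up
throughout, with the 0.1 FDR threshold as the default significance
level.

## Synthetic cohorts

The generator draws a per-gene base log2 mean b_g ~ N(4, 1.5), adds an
independent per-tissue shift ~ N(0, separation = 1.0), and silences a
sparsity = 0.1 fraction of genes per tissue (log-mean −3, i.e. near-zero
linear expression) to mimic tissue-specific silencing.  Samples are
lognormal around the tissue log-mean with noise sd 0.5.  Tumors mix the
OT and TT log-means with weight α (default 0.2 for primaries, 0.5 for
metastases, so metastases have drifted further toward the target — the
structure the analysis is designed to detect; setting both equal gives
a "no-shift" null) plus a cohort-level tumor-specific offset
~ N(0, 1.0) shared by all samples of a cohort.  Purity confounding,
when enabled, mixes each observed sample as
purity·tumor + (1 − purity)·OT on the linear scale with
purity ~ Beta(5, 2) (mean ≈ 0.71, the typical bulk-tumor range).
Planted pathway shifts redraw only a gene set's genes at a different
mixture weight α_p, keeping the cohort offset, so α_p equal to the
cohort's own α changes nothing but noise.

What the generator does *not* emulate: count-level sampling noise
(values are continuous lognormal), gene–gene correlation beyond the
shared tumor offset, batch effects, single-cell dropout, and realistic
pathway co-expression.  Passing tests therefore demonstrate the
statistical machinery — calibration of the empirical nulls, recovery of
planted effects, confounder removal — not performance on any real
cohort.

## Problem sizes and numerical choices

Validation runs use 400–1,000 genes, 8–30 patients per cohort, and
2,000 null iterations — large enough for the calibration and recovery
properties being checked while keeping the full suite fast; production
runs default to 10,000 iterations (seed 1206, overridable).  The null
calibration check uses four independent single-class cohorts
(200 random "pathways" each, 800 p-values total) and requires the
Kolmogorov–Smirnov distance from uniform to stay below 0.05.  Gene
order after harmonization is the sorted intersection; variable-gene
ties are broken lexicographically; duplicate gene rows collapse by mean
with a warning, while duplicate sample ids are a hard error.

## Known limitations

- Pathway-level values are defined on the Euclidean measure only; the
  Spearman/cosine measures apply to whole-transcriptome ratios.
- The empirical null conditions on the gene-set size, not on gene
  identity; co-expressed pathways can be conservative or
  anti-conservative relative to a structure-aware null.
- Purity residualization assumes a linear purity effect on the ratio;
  strongly nonlinear confounding leaves residual rank correlation.
- The `inf` sentinel policy drops degenerate samples from group
  medians; cohorts dominated by degenerate samples produce NaN medians
  with a logged count rather than an error.
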