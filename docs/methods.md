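# Methods

`livpm` re-implements, as a tested desk-scale pipeline, the comparative
molecular analyses used to contrast prefrontal-cortex tissue from living
surgical biopsies (LIV) with postmortem donor tissue (PM): differential
expression of primary RNA, mature RNA and protein; differential splicing
rate; differential intron usage over intron clusters; TMT proteomics
preprocessing; and RNA-protein differential co-expression with a
permutation null. Raw study data are not packaged; every analysis is
exercised on synthetic data whose generating parameters are known, so the
tests measure recovery, calibration and oracle agreement rather than
biological replication.

## Synthetic data model

The generator reproduces the structural features the analyses depend on,
not the biology.

**Cohort.** `n_liv_individuals` living participants (default 171), of whom
a `bilateral_fraction` (default 117/171) contribute two hemispheric
samples sharing an `individual_id`; `n_pm_individuals` postmortem donors
(default 246) contribute one sample each. Covariates exist to exercise
covariate adjustment, not to be realistic: sex ~ Bernoulli(0.5), age ~
N(60, 10) years clipped to [18, 95], a RIN-like score ~ N(7, 1) clipped to
[4, 10], a neuronal-fraction-like proportion ~ Beta(5, 5), and a
round-robin batch label.

**RNA counts.** Negative binomial with gene-wise log-normal baselines and
a common dispersion (default 0.1, var = mu + 0.1 mu^2 — a standard bulk
RNA-seq assumption; the study's real dispersion is unknown and this is a
free parameter). For gene g in group G:

    log2 mu_primary = b_g - s_g/2 + (beta_g - delta_g/2)[G=PM] + u_gi + d_s
    log2 mu_mature  = b_g + s_g/2 + (beta_g + delta_g/2)[G=PM] + u_gi + d_s

`beta_g` is the shared expression log fold change (positive = higher in
PM; +/- `logfc_scale` for a `de_fraction` of genes), `delta_g` the
splicing-rate shift, i.e. the log2 difference in mature:primary ratio
between groups (+/- `splice_shift_log2` for a `splicing_shift_fraction` of
genes), `s_g` > 0 a mature/primary abundance gap, `u_gi` ~ N(0, 0.3) a
per-gene individual intercept shared by bilateral replicates, and `d_s` a
per-sample depth offset. True per-modality logFCs (beta -/+ delta/2) and
deltas are recorded as ground truth.

**Protein ratios.** Log2 sample-to-reference values: group effect +
per-(protein, multiplex) additive batch effect ~ N(0, `protein_batch_sd`)
+ N(0, `protein_noise_sd`) noise. Samples are assigned to `n_multiplexes`
(default 34, sizes 14-16 at the default cohort) by ranking on
`gamma*[G=PM] + U(0,1)`: `multiplex_group_confounding` gamma = 0 gives
composition independent of group, 1 gives group-pure multiplexes.
Missingness is a configurable mixture of missing-completely-at-random and
abundance-dependent cells (lower latent abundance, more missing), with
per-protein rates rescaled so the expected overall rate equals
`missing_rate_target` (default 0.397); at matrix sizes >= 10^6 cells the
realized rate lands within +-1% of the target.

**Junctions.** Each cluster is a star of 2-10 introns sharing a start
coordinate on a synthetic contig (0-based half-open, stated in the file
headers), so clustered introns always share an endpoint. Per sample a
negative-binomial cluster total is split multinomially by the group's
usage vector; shifted clusters give PM samples a cyclic rotation of the
LIV vector. Decoy introns exercise the filters: low-contribution decoys
carry ~3% of cluster reads, high-zero decoys are zeroed in a fraction of
samples. What the generator does not emulate: non-star cluster topologies
at generation time (pruning is tested on explicit adversarial fixtures
instead), annotation ambiguity, and overdispersed per-sample usage.

**Limits of what passing tests show.** The generators match the analyses'
assumptions by construction (NB counts, additive batch, Gaussian
residuals). Passing recovery and calibration tests therefore demonstrates
correctness of the implementations under those assumptions, not robustness
to real-data violations (outlier samples, variance heterogeneity,
annotation error).

## Differential expression and splicing rate

Counts are normalized to log2 counts-per-million with trimmed-mean (TMM)
scaling factors (30% log-ratio trim, 5% abundance trim, precision
weights, factors rescaled to unit geometric mean) and a 0.5 count offset.
Low-expression filtering drops features whose natural-log mean TPM-like
abundance is below -5 (the threshold's log base is not fixed by the source
description; natural log is the default and the base is configurable).

The reference workflow fits precision-weighted linear mixed models. This
package deliberately fits unweighted models: a per-feature
random-intercept mixed model (statsmodels MixedLM) is available
(`method="mixed"`), but the default replicate strategy averages each
individual's replicate columns and then runs one vectorized OLS pass
(`method="average"`). For balanced replicate designs the group
coefficient is identical, the estimand (group difference on the log2
scale) is unchanged, and the vectorized path is what makes the
simulation-based calibration tests affordable; the two paths agree to
r > 0.98 on synthetic data. Observation weights and empirical-Bayes
variance moderation are intentionally out of scope.

Positive logFC always means higher in PM. Features with BH-adjusted
p < 0.05 are DEFs: LIV DEFs (logFC < 0) or PM DEFs (logFC > 0).

Differential splicing rate stacks the primary and mature matrices two
ways: long (2G x S) to compute one TMM factor per sample from the joint
library, and wide (G x 2S, one column per sample x spliced status) for
fitting. Per gene, the model is

    log2 CPM ~ spliced * group (+ covariates)

and the spliced:group interaction estimates the log2 difference in
mature:primary ratio, PM minus LIV. Genes with an all-zero spliced-by-group
stratum are excluded and reported. The fit is antisymmetric under group
relabeling, which the tests assert exactly.

## Intron clusters

Introns are edges; start/stop coordinates (per contig and strand) are
vertices; a cluster is a connected component. Defaults follow the
reference pipeline: minimum intron length 50 bp, maximum span 500,000 bp,
>= 50 supporting reads per cluster. Intron filters: zero counts in >= 25%
of samples, or < 5% contribution to the cluster total; both statistics are
computed in a single pass on pre-removal totals (whether contributions
should be recomputed after the zero-rate removal is not specified; the
single-pass choice is documented here and deliberately matched by the test
oracle). Reassessment then removes single-edge clusters, keeps
still-connected ones, and otherwise decomposes the cluster: all maximal
components are retained (ties become separate clusters), smaller ones are
pruned, and a final size filter keeps 2-10 introns. The procedure is
idempotent and is checked against an independent brute-force
connected-components oracle on randomized fixtures.

The per-cluster differential usage test is a deliberate simplification of
the Dirichlet-multinomial model used at full scale: a chi-square test on
the group x intron summed count table, with a seeded label-permutation
fallback whenever an expected cell drops below 5. Eligibility mirrors the
reference tool: LIV samples are first downsampled to one per individual
(seeded random pick), and a cluster is tested only if both groups have
>= 10 samples with cluster reads and every intron is nonzero in >= 10
samples. Because the chi-square treats reads as units, it is calibrated
when usage vectors are constant within groups (as in the generator's null)
and will be anticonservative under per-sample usage overdispersion — a
known limitation of the simplification.

## Proteomics preprocessing

Fixed order, each stage reporting into a QC record:

1. **Median alignment**: each sample's observed median shifted to 0.
2. **Inter-multiplex outlier scan**: per protein x multiplex, a Welch
   t-test of values inside vs outside the multiplex; p-values transformed
   as log(-log p); blocks beyond 4 SDs from the median of all transformed
   values (two-sided) are blanked. This rule is extremely conservative by
   construction — on a null matrix the flag rate is effectively zero, and
   only blocks with p below roughly 1e-50 can fire — which matches its
   role of catching catastrophic quantification failures only. The exact
   form of the "double log" transform is a documented reading; the 4-SD
   rule is applied two-sided.
3. **Batch correction preserving the group effect**: per protein, an
   additive model `value ~ group + multiplex` is fit on that protein's
   observed cells and only the centered multiplex component is
   subtracted; the LIV-PM effect and residuals pass through and the
   missingness mask is untouched. Two deviations from the reference
   ComBat workflow are intentional: no empirical-Bayes shrinkage of batch
   parameters (at these sample sizes shrinkage changes little; the
   essential contract is "remove batch, keep group"), and no temporary
   imputation before the fit — imputed cells carry no protein-specific
   batch signal, so fitting on completed data attenuates batch estimates
   by roughly the missing fraction, whereas the observed-cell fit removes
   >= 95% of injected shifts while recovering group effects within 10%.
4. **Missingness filter**: proteins observed in >= 50% of samples.
5. **KNN imputation**: a missing cell takes the mean of the k = 10 most
   correlated proteins (correlation distance over shared observed
   samples) observed in that sample; observed cells are never modified;
   proteins without usable neighbors fall back to the protein mean and
   are flagged. The same KNN contract stands in for the reference
   ensemble imputation, which is out of scope.

## Co-expression

Residual matrices are computed by OLS per feature against caller-supplied
covariates (the RNA preset for co-expression omits the neuronal-fraction
covariate: cell-type effects cannot be removed from the protein side, so
they are deliberately left in the RNA side; the DE preset includes it).
Per group, the RNA x protein Pearson matrix is computed with two-sided
t-distribution p-values, BH-adjusted across all RNA x protein tests within
the group.

The differential co-expression statistic is |corr_PM - corr_LIV|. Its
null: each permutation splits LIV in half and PM in half (floor/ceil for
odd sizes, the larger LIV half joined to the smaller PM half), forms two
mixed groups, and recomputes the statistic. One shared set of splits
serves all pairs (drawing independent splits per pair would be
computationally incoherent at matrix scale; this sharing is an assumption,
documented here). The empirical p is the plain exceedance fraction —
strictly greater, ties count against rejection, resolution exactly
1/n_perm, p = 0 possible; a (1+k)/(1+N) correction is available behind a
flag, default off. Calibration on an exchangeable null holds the type-I
error at 0.05 +/- 0.01 with n_perm = 1000. Full-scale per-pair
permutation (~2e8 pairs x 1e4) is cluster-scale; the shipped defaults
target matrices of a few hundred features by a few hundred samples.

Enrichment uses 2x2 tables: significance-in-either-group (BH-adjusted
p < 0.05) against differential (empirical p < 0.05), with the odds ratio
computed by the sample formula OR = (a/b)/(c/d) and Fisher's exact test on
the same table (a zero cell switches to the conditional estimate and is
flagged). Same-gene enrichment is one-sided on same-gene x
(positive-and-significant), with significance defined on the full-matrix
adjustment before any subsetting. The regression of same-gene correlations
on mature-RNA and protein logFCs uses OLS per group with a Bonferroni
factor of exactly 4. Family enrichment restricts the background to pairs
significant in either group, decides membership by the pair's protein,
skips sets with fewer than 10 member proteins in the data, and
BH-adjusts across tested sets.

## Covariate screen

PCA runs in sample space on a residual matrix; each covariate (numeric
as-is, categorical dummy-encoded) gets its first canonical correlation
with each of PCs 1-5. The screen reports and ranks; it never auto-selects
a covariate — covariate selection is a human review step by design.
Outliers are samples whose Euclidean distance from the (PC1, PC2) centroid
exceeds mean + 3 SD of distances; PC scores are standardized before the
distance (whether to scale is not fixed by the source description), and a
per-axis variant is available behind a flag.

## Numerical conventions

- BH: standard step-up with cumulative minimum; NaN p-values are excluded
  and returned NaN.
- Percentages in summaries: rounded half away from zero to the nearest
  integer (one decimal for the differential co-expression fraction).
- Binary traits: the second sorted level is coded 1, so LIV/PM labels give
  positive coefficients for PM.
- Zero-variance features are excluded from DE with a warning; a
  zero-total sample is an error naming the sample; collinear covariates
  are an error naming a culprit pair.
- Determinism: every generator draws from `default_rng([seed, stream])`
  with a fixed stream id per generator, so one config seed reproduces the
  whole bundle bit-for-bit.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run at desk scale by choice:
cohorts of 40-240 samples, hundreds of genes/proteins, tens to hundreds
of clusters, n_perm = 1000, 100-replicate null studies. These sizes hold
the estimator properties being tested (the statistics concentrate well
below the asserted tolerances) while keeping the full suite in the
tens-of-seconds range.
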