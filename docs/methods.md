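# Methods

This note records the models, conventions and numerical choices behind
`myoaging`, and what the synthetic-data tests do and do not establish about
real data.

## Study design the package assumes

A cross-sectional two-cohort design: healthy controls spanning a wide age
range (default 17–89 y, n = 75) and disease-mutation carriers spanning
mid-life (default 31–74 y, n = 22), profiled on a log2-scale expression
platform, with sample-level age, sex, cohort and stage metadata. All
expression input is assumed already log2; background correction and raw
array processing are upstream of this package.

## Preprocessing

*Quantile normalization.* Each column is replaced by the vector of row-rank
means at its own ranks. Ties within a column receive the mean of the tied
positions' rank-means, which makes the transform deterministic and
order-independent. A consequence worth knowing: collapsing a tie changes
that column's value multiset, so the transform is strictly idempotent only
for tie-free columns (real-valued intensities in practice). Column means
are exactly equal after normalization regardless of ties.

*Probe collapse.* One probe per gene, keeping the probe with the highest
mean expression across samples (ties broken by lexicographically smallest
probe id). This is the common microarray convention; it is a convention,
not an inference, and is configurable by pre-filtering the annotation.

## Differential expression

The two-group comparison uses the classical empirical-Bayes moderated t.
Per-gene pooled variances s²_g on d = n_A + n_B − 2 df are assumed scaled
chi-square around a gene-specific σ²_g, with an inverse-chi-square prior
(d₀, s₀²) shared across genes. The prior is estimated by method of moments
on z = log s²_g: E[z] and Var[z] of log chi-square variates are matched via
digamma/trigamma, with d₀ recovered through a Newton inversion of the
trigamma function. If the observed spread of z does not exceed the
chi-square floor, d₀ = ∞ and every posterior variance equals s₀² (with the
log-bias correction retained). The moderated t uses the posterior variance
s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) and d₀ + d degrees of freedom. The whole
chain reproduces limma's `eBayes` to ~1e-14 on shared fixtures (verified
against Rscript in the test suite); a plain pooled-Student or Welch t is
available with `moderation=False`.

Age matching is the caller's job (pass age-matched groups via the metadata
column); the DE model itself carries no covariates. The default
significance gate is p ≤ 0.01, with BH q-values reported alongside
(statsmodels' `multipletests` behind the `bh_fdr` surface, verified against
a brute-force step-up).

## Concordance

Significance is p ≤ threshold per table; direction is the sign of the log2
fold change. Genes with a fold change of exactly 0 have no direction and
are excluded from the percentages (counted and logged) rather than assigned
a side. Undefined percentages (empty overlap, no concordant gene) are
reported as `None`, never 0.

## Concept enrichment

Weights are normalized to each concept's maximum, so the top-associated
gene scores exactly 1. The exclusion filter is a conjunction: a gene is
dropped only when its normalized weight is < 0.1 *and* p > 0.05 in both
contrasts; either strong association or significance anywhere rescues it.

The reference distribution for the KS test is genuinely a free choice; the
default is the two-sample test against the background of all other measured
genes' weights for the same concept, which matches how a right-shifted CDF
is read against the rest of the transcriptome. A one-sample test against
Uniform[0,1] is available (`reference="uniform"`). p-values use the
asymptotic Kolmogorov distribution by default, with `exact=True` for small
sets; the significance gate is p < 10⁻³. The D statistic is computed by
scipy and cross-checked in the tests against an exhaustive max-gap oracle
over all jump points.

## Trend profiles, clustering, acceleration

A trend profile is the vector of per-gene mean expression over equal-count
(quantile) age bins, z-scored across bins (population SD). Standardization
deliberately removes level and amplitude so Euclidean k-means compares
trajectory *shapes*; the per-gene OLS slope (log2 units/year over all
cohort samples) is carried alongside and is the quantity accelerated calls
are made from. Constant genes get an all-zero profile and a flag. Bins that
cannot be filled because of duplicated ages are merged with a warning.

k-means is a seeded Lloyd iteration with k-means++ initialization; the
within-cluster sum of squares is non-increasing by construction and the
implementation exposes its objective trace. Empty clusters are re-seeded at
the farthest point. The silhouette gate: for k = 2…20 and a fixed number of
restarts per k, accept the first partition in which *every* cluster's mean
silhouette S_avg ≥ 0.6; otherwise return the best partition (highest
overall mean silhouette) flagged `accepted=False`. Silhouette conventions:
singleton clusters score 0, and so do points whose a and b are both 0
(all-identical degenerate geometry).

Acceleration calls per gene, with r = β_carrier/β_control and thresholds
ratio ≥ 1.5 and |slope| ≥ 0.005 log2/y (flat gate): accelerated,
decelerated, concordant, discordant (sign flip) or flat. Two edge choices:
a gene flat in controls but trending in carriers is called accelerated (a
trend present only in carriers is a faster-than-aging change), and a gene
trending in controls but flat in carriers falls out as decelerated through
the ratio. Cluster-level summaries report the majority label per cluster.

## Age regression

All fits are OLS with sex as an additive binary covariate (female = 1),
dropped with a warning when constant. The piecewise model is two
*independent* linear fits below/above a fixed breakpoint (default 42.5 y,
the young/mid-life split) with no continuity constraint — the breakpoint is
chosen, not estimated. Each segment requires ≥ 4 samples. Noiseless inputs
are recovered to machine precision (perfect fits report p = 0 rather than
NaN). Fold-change responses are fitted on the fold-change scale as given;
re-log the response upstream if a log-linear reading is wanted.

## Assays

ΔΔCt: ΔCt = target − housekeeping per sample; ΔΔCt subtracts the *mean*
ΔCt of the reference group (no per-pair matching); FC = 2^−ΔΔCt with
amplification efficiency fixed at 2. Fold changes are invariant to any
global Ct shift. The group summary reports both 2^(−mean ΔΔCt) and the
mean/SD of per-sample fold changes.

Fusion index: 100 · (nuclei inside MHC-positive objects)/(total nuclei) —
the plotted percentage definition; nuclei-per-myotube is a secondary
output when myotube counts are supplied. JC-1: red/green per perinuclear
compartment; zero-green compartments are excluded and counted, never
imputed.

## The synthetic generator

Expression of gene g in sample s is

    baseline_g + β_{g,cohort(s)}·(age_s − age_min) + sex_effect·1[female] + ε,
    ε ~ N(0, σ²),

with age_min the minimum over both cohort ranges (so concordant genes lie
on one shared trajectory), ages uniform over each cohort's range, and gene
classes assigned deterministically by count (floor of fraction·n_genes,
remainder to null) so fixture counts are exact. Defaults: σ = 0.3 log2
units, sex_effect = 0.1, acceleration factor α = 2, base slope
0.04 log2/y. The base slope was set by effect-size reasoning: the
decelerated class carries slope β/α, and at σ = 0.3 with ~60 samples per
cohort the per-cohort OLS slope SE is ~0.002–0.003 log2/y, so β = 0.04
keeps even the shallowest planted trend estimable; it corresponds to a
strong aging gene (~3-fold change over 40 years). Concept weights: Beta(5,1)
for planted-enriched genes vs Beta(1,5) background. Clinical scores:
MRC = 5 + β(age − age_min) + sex_effect + noise, clipped to [0,5] and
rounded to the 0.5 grid (disable with `grid=None`). qPCR targets sit
log2(FC) cycles below the reference Ct over a flat housekeeping gene.

What the generator does *not* emulate: batch effects, probe-level bead
noise, heteroscedastic or heavy-tailed noise, non-uniform age
distributions, family structure among carriers, and correlated genes.
Passing recovery tests therefore demonstrate correctness of the estimators
under the stated model, not robustness to those real-data features.

## Numerical notes and limitations

- Ties in quantile normalization break strict idempotence (see above).
- The trigamma inversion uses Newton iteration to 1e-12 relative tolerance.
- k-means termination: assignment fixed-point or 300 iterations; gating is
  bounded by k ≤ 20 and the restart budget, so it always terminates.
- A ±2·SE interval around an OLS slope at n ≈ 33 covers the truth ~94.5%
  of the time (the pivot is t-distributed, not normal); expecting the
  normal 95.45% from "2 SE" at these sample sizes overstates coverage.
- The MRC ceiling (scores clipped at 5 near the youngest ages) attenuates
  clinical slope estimates slightly; the rounding grid adds quantization
  noise that the fit absorbs into its residual SE.
- Sizes used in the shipped simulations (200 trend genes, 60 samples per
  cohort, 10-seed panels; 5000-gene null; 200-seed clinical panels) were
  chosen as the smallest designs at which the recovery rates stabilize.
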