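# Methods

This note records the statistical model behind each stage, the defaults
and why they are what they are, what the synthetic data does and does
not emulate, and the numerical choices a maintainer would want spelled
out.

## Coordinate model

All intervals are 0-based, half-open.  Transcript coordinates always run
5′→3′: position 0 of a minus-strand gene is its *highest* genomic exonic
base, so no downstream stage branches on strand.  Genes without
annotated UTRs carry zero-width UTR segments; a GTF gene without CDS
features is treated as all-CDS with a logged warning.  Duplicate exon
lines are deduplicated with a warning.  Bins are laid on the union-exon
gene body ("gene" rather than one transcript per gene): this is strand-
and intron-robust and matches how the metagene is anchored.  Boundary-
spanning reads go to the bin containing the midpoint of their projected
span — each read counts exactly once per overlapping gene, so bin totals
are conserved; a read overlapping two genes counts once in each.

## Differential methylation

**Size factors.** Median-of-ratios (median over all-positive features of
count / feature geometric mean), rescaled to geometric mean 1; total-
count fallback with a warning when no feature is positive everywhere.
The estimator is scale-equivariant and consistent with the NB testing
framework.

**Input adjustment.** The IP signal of bin *b* in gene *g* for sample
*s* is divided by the subject's *relative* expression
`(INPUT[g,m(s)]/f_m + c) / mean(INPUT[g,·]/f + c)` with pseudo-count
`c = 1` guarding zero input genes; `m(s)` is the input library of the
same subject and condition.  Equal expression across samples makes the
adjustment an identity; a subject at twice the mean expression has its
IP halved.  The acceptance run quantifies what this buys: on
DE-only simulations the unadjusted route calls ~80% of candidate regions
"differentially methylated" while the adjusted route stays under the
nominal 5%.

**Filters.** (1) mean adjusted IP < 10 in both CTRL and CASE → dropped;
(2) per-base adjusted IP signal (bin mean / bin width) below the
per-base normalized input gene signal (gene mean / transcript length) in
both groups → "not enriched in IP".  The enrichment ratio (default 1.0)
is configurable since "enriched" admits several readings.

**NB Wald test.** Per bin, a negative-binomial GLM with log link fitted
by batched IRLS (shared design across bins; max 100 iterations,
deviance tolerance 1e-8).  Designs: paired =
`intercept + subject indicators + condition`; covariate =
`intercept + covariates (standardized / dummy-coded) + condition`.
Fractional adjusted counts are rounded half-even before the likelihood
fit (a continuous quasi-likelihood-style fit is available via
`round_counts=False`).

**Dispersion.** Per-bin Cox–Reid adjusted profile likelihood evaluated
on a 25-point log-spaced grid over α ∈ [1e-4, 10] (β re-fit at every
grid point, warm-started; quadratic refinement of the maximum).  The
mean–dispersion trend is a lowess through the per-bin log-MLEs whose
*level* is re-anchored: a constant log-offset is chosen to maximize the
*summed* CR-adjusted profile likelihood across bins.  This matters: at a
dozen observations the per-bin log-dispersion MLE is noisy and
left-skewed, so a lowess through it sits systematically low, which
deflates Wald standard errors; the pooled-likelihood offset is the
common-dispersion MLE for a flat trend and is close to unbiased.
Per-bin values are then shrunk 50/50 (log scale) toward the trend and
floored at it — downward deviations from the trend at this sample size
are sampling noise, and trusting them is exactly what anti-conservative
small-sample NB pipelines do.  With this scheme the paired n = 6 null
holds type-I error at ~0.04–0.05 at p < 0.05 with a standard-normal Wald
reference (no t correction).

**Region calling and FDR.** Bins with raw p < 0.05 (configurable), same
gene, consecutive ordinals and same fold-change sign merge into maximal
runs; `--ignore-sign` disables the direction requirement.  Per-bin
p-values combine by Fisher's method (p = 0 clamps to the smallest
positive float, logged).  BH is applied to region combined p-values with
multiplicity equal to the **number of bins tested**, not the number of
candidate regions: candidates are pre-selected at the bin threshold, so
their combined p-values are bounded near the threshold by construction
and BH over candidates alone would call essentially everything under a
global null.  With bin-count multiplicity the realized false-call rate
of regions on null simulations stays below nominal (measured ~0.02–0.03
at q < 0.05) while planted 2-bin regions at one log2 unit are detected
with ~55–65% sensitivity and 100% direction accuracy at n = 6 pairs.
Fisher's independence assumption across adjacent bins is knowingly
violated by construction; the null simulation measures the realized rate
under that dependence rather than assuming it away.

**Batch removal for PCA.** Features are regressed jointly on
[retained | nuisance] designs and only the fitted nuisance component is
subtracted (the retained effects and grand mean survive); confounded
designs are rejected.  PCA is column-centered SVD.

## Expression DE

The input-library route reuses the NB Wald machinery on gene-level
counts with covariates.  The count RNA-seq route is: CPM filter (presets
`nod-beta`: CPM > 1 in ≥ 3 samples; `oas-oe`: CPM > 0.49 in ≥ 4), TMM
factors (double trim 30%/5%, precision-weighted, reference = sample with
upper-quartile closest to the mean), logCPM with prior count 0.5 and
effective library sizes, and moderated t: per-gene OLS, residual
variances shrunk toward a prior via the scaled-F moment-matching
estimate of (d₀, s₀²) (inverse-trigamma Newton solve), t on d₀ + d_g
degrees of freedom.  Voom precision weights are deliberately not
implemented: at the simulated depths the weights change little, and the
moderated-t machinery is the part worth owning and testing.  Degenerate
prior estimation falls back to the ordinary t (logged).  The DEG×DMG
table classifies genes into hyper/hypo × up/down; genes with regions in
both directions count in each matching cell and are flagged.

## Single cell

QC thresholds are inclusive (a cell at exactly 2000 counts, 1000 genes,
10% mito passes) — a declared convention, since strictness is not
derivable.  Normalization is a simplified two-level deconvolution:
k-means clusters on logCPM-PCA (clustering is only a device for
normalization), within-cluster factors as median ratios against the
cluster pseudo-cell (mean profile), rescaled across clusters by
pseudo-cell library sums, floored at the smallest positive value if
degenerate, mean 1.  The full linear-system pooling estimator is out of
scope; the simplification preserves the within/between-cluster
structure and recovers simulated depths within ~5% median relative
error.  HVGs rank by total variance of log2(count/factor + 1) minus a
delta-method Poisson technical term `μ/(ln2²·(μ+1)²)·E[1/s]`; the
approximation is rough below μ ≈ 1, which is why the null-calibration
test allows a small residual.  β-calling fits a K = 4 univariate
Gaussian mixture (scikit-learn EM, k-means++ init, 20 restarts, fixed
seed), ranks components by mean, and calls the top two modes β — the
output is invariant to EM label order.  β-cell DE drops genes expressed
in < 10 β-cells and runs the moderated t on log-normalized values, with
CASE vs CTRL as the reported direction.

## Bench formulas

ΔΔCt aggregates replicate Ct by arithmetic mean (Ct is already
logarithmic; geometric averaging would double-log).  The colorimetric
m⁶A% and LC-MS standard-curve computations are direct algebra with
guardrails (negative sample−NC clamps to 0 with a warning; PC ≤ NC and
zero-slope calibrations are errors).  Decay regression is forced through
the origin because series are normalized to t = 0; a free-intercept
variant is behind a flag, as is per-timepoint normalization to a control
arm.  k ≤ 0 reports "stable" with infinite half-life rather than a
negative rate.

## Synthetic data

One root seed is split into independent per-generator streams via numpy
`SeedSequence` spawn keys, so any module's inputs can be regenerated
alone.  The MeRIP generator draws gene baselines lognormal(log 300,
0.5²), gene-wise subject effects Normal(0, 0.2²) on the natural-log
scale (shared between a subject's libraries — visible but not dominant,
which is what makes the paired test demonstrably tighter than the
unpaired one), library factors uniform in [0.7, 1.4], NB dispersion
α = 0.1, and per-gene peak runs of 1–3 adjacent bins at 4× the
background per-bin IP propensity (background 0.5×, so non-peak bins fail
the enrichment filter and peaks clear it).  DM effects multiply CASE IP
means by 2^±lfc on the peak run; DE effects multiply both assays'
means.  Defaults mirror the paired design at 15 subjects; the
case-control preset uses 20 controls vs 7 cases with batch/gender/age/
BMI columns and an optional additive batch shift.  The single-cell
generator draws insulin log-expression from a 4-mode mixture
(means 0/2/4/6, sd 0.3, equal weights; modes 3–4 are β in truth) and
writes insulin counts that reproduce those values after depth scaling;
planted fractions of cells violate each QC rule.  Assay tables follow
the stated forms Ct = c₀ − log2(expr) + ε, A(t) = e^(−kt)(1+ε), OD
linear in analyte.

What the generators do **not** emulate — and hence what green tests do
not certify on real data: alignment/mapping artifacts, fragment-level
coverage autocorrelation within bins, GC and length biases, multi-isoform
genes, batch×condition interactions, ambient RNA and doublets in the
single-cell arm, and amplification-efficiency differences in qPCR.

## Problem sizes

Simulation-backed tests and the acceptance script use 200 genes × ~10
bins at 6 subject pairs (50 replicates for null rates, 25 for the
adjustment comparison), 2000 features for calibration checks, and 1000
cells × 1500 genes for the single-cell arm — sizes chosen so the full
suite runs in well under a minute while leaving every rate estimate
with a usable Monte-Carlo SE.  The number of merged-region candidates
per null replicate (~25) makes pooled rates stable to ±1–2 points.

## Known limitations

* The Wald test's calibration rests on the trend-anchored dispersion;
  with very few bins (< ~50) the pooled offset itself is noisy.
* Fisher combination over correlated adjacent bins is anti-conservative
  in principle; the selection-aware BH multiplicity absorbs this in
  practice (measured, not proven).
* The realized FDR of region calls on *signal-rich* simulations can
  exceed the nominal level somewhat (BH adapts its threshold to the many
  true discoveries while the false candidates inherit the tail
  miscalibration of small-n Wald p-values); the null and DE-confound
  settings are the controlled guarantees.
* Motif ranking by fold enrichment favors rare high-fold k-mers when
  the contrast is weak; consumers should read the q-value column, and
  the analysis driver reports the top *significant* motif.
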