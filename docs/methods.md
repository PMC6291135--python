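# Methods

## Setting and data model

The package analyses a paired design: DNA from each of `n` subjects is
processed by each of `k` laboratory methods (the motivating case is
whole-blood DNA extraction, with three methods on ten subjects) and profiled
genome-wide for CpG methylation, giving a sites × samples matrix of
beta-values in [0, 1]. The central object, `BetaDataset`, couples that
matrix with per-site genomic annotations (chromosome, 1-based position, CpG
context) and a sample sheet (subject, method, chip position, DNA yield and
purity ratios). All analyses assume the matrix has already been normalized
upstream; the package does not perform background subtraction or
between-array normalization.

### Site filtering

`filter_sites` removes sites by five list-driven rules applied in a fixed
order — blacklist, detection p-value (any sample above the threshold,
default 0.01), non-CpG context, missing values, excluded chromosomes
(default chrX/chrY) — and reports exclusive counts: a site failing several
rules is counted once, under the first. The order is a convention; the
counts (but not the retained set) depend on it. Iterative detection-p
algorithms that drop probes and samples jointly are out of scope; the
threshold rule here is per-site and list-driven.

## Heteroscedastic Bland–Altman model

For a method pair, every subject–site contributes a point
(x, d) = ((β₁+β₂)/2, β₁−β₂). The model is

    d_i = σ(x_i) e_i,   e_i ~ N(0, 1),   σ(x) = exp(a + b (x − ½)²)

The exponential form keeps σ positive for any (a, b); with b < 0 the spread
peaks at x = ½ and decays symmetrically toward the boundaries, which is the
empirically observed shape for beta-value differences. There is no bias
term: the model centres differences at zero, and the empirical mean
difference is always reported alongside the fit (`VarianceModelFit.mean_d`)
because classical Bland–Altman centres its limits on it.

**Estimation.** (a, b) minimize the Gaussian negative log-likelihood
Σᵢ [a + b·uᵢ + dᵢ²·e^(−2(a+b·uᵢ))/2] with uᵢ = (xᵢ−½)². The likelihood is
smooth and two-dimensional; L-BFGS-B with the analytic gradient is started
at a₀ = ½·log(mean d²) (the constant-variance MLE) and b₀ = 0, with an
objective tolerance of 1e-8. Non-convergence is reported via the
`converged` flag and a warning, never silently. If all x coincide, b is
unidentifiable and is fixed at 0, which reduces a to the closed form
exp(2a) = mean(d²) — this closed form and a dense grid search serve as
independent oracles in the test suite. The fit uses all points by default
(a few million points is cheap for a 2-parameter problem); a seeded uniform
subsample is available for interactive use.

**Limits of agreement** are ±z·σ̂(x) with z = 1.96, covering ~95% of
differences when the model holds (verified by Monte-Carlo in the tests).

**Normality screen.** Genome-scale difference vectors defeat any single
normality test, so the screen draws (by default) ten seeded subsamples of
5,000 points without replacement and records one Shapiro–Wilk p-value each.
Gaussian differences yield comfortably non-significant medians; the
bimodal-x heteroscedastic mixture is rejected in all repeats.

**Difference distribution.** Per site, the difference is averaged over
subjects and its absolute value binned into half-open intervals [0, 0.01),
…, [0.09, 0.10), [0.10, ∞); the table reports percentages of sites per bin.
Half-open edges are a convention choice (published tables of this kind do
not state edge handling); percentages sum to 100 exactly before rounding.

## PCA and covariate screening

PCA treats samples as observations and sites as variables, site-centred by
default (optional site-scaling; beta-values share a scale so scaling is off
by default). Scores and variance fractions come from the SVD of the
processed matrix, with fractions defined as squared singular values over
total variance, so all min(n−1, p) components sum to 1. Each retained
component is tested against each covariate: Kruskal–Wallis (tie-corrected,
chi-square p) for categorical covariates, two-sided Spearman for numeric
ones. The Bonferroni family is per covariate across components
(p_adj = min(1, m·p) with m the number of components tested) — the stricter
of the plausible family definitions. By default all n−1 components are
tested, so in a 30-sample design weak signals on late components (PC 10–12)
remain reachable. Exact variance-fraction values depend on upstream
preprocessing conventions, so cross-study comparisons of these fractions
are tolerance-based, not exact.

## Differential methylation

* **Global:** each subject's genome-wide mean beta per method; paired
  t-test on the n per-subject differences (df = n−1). All-zero differences
  give t = 0, p = 1; zero variance around a non-zero mean leaves t
  undefined (reported NaN, with a warning).
* **Per CpG:** vectorised paired t-tests, two-sided, with BH step-up FDR
  across all sites; zero-variance sites are excluded from the BH family and
  their count logged. Significance is FDR < 5%.
* **Regions (bump hunting):** sites are grouped into clusters (new cluster
  at a chromosome change or a gap > maxGap, default 1000 bp; a gap of
  exactly maxGap stays together, matching the cited clustering convention).
  The per-site effect (mean paired difference) is loess-smoothed within
  clusters of ≥ 7 sites (span 0.75 over within-cluster positions; smaller
  clusters keep raw effects; a loess failure falls back to raw effects with
  a warning). Candidate regions are maximal same-sign runs with |smoothed
  effect| ≥ cutoff (default 0.01); a region's area is the sum of |smoothed
  effect|. The null distribution flips each subject's whole difference
  vector's sign independently with probability ½ — exchangeable under the
  paired null — for n_boot seeded draws (default 250), and
  FWER(region) = fraction of draws whose genome-wide maximum null area
  reaches the observed area. Significance is FWER < 5%.

  This is a deliberately simplified variant of Bumphunter-style region
  detection: the two-group paired design admits the sign-flip bootstrap in
  place of the original's linear-model residual bootstrap, and the
  max-statistic FWER replaces its pooled-null-area tally. Smoothing span
  and minimum cluster size are package choices. Because lowess with zero
  robustness iterations is linear in the response, clusters smaller than
  the bootstrap count are smoothed through a precomputed smoother matrix
  (one lowess call per site, then matrix–vector products per bootstrap);
  larger clusters call lowess per replicate. The two paths are numerically
  identical.
* **Directional summaries:** for three methods, per-CpG results of all
  three pairs are tabulated by p-value group (p < 0.002, p < 0.01,
  p > 0.75 by default): the sign table gives, per pair and group, the
  percentage of sites with the first method higher/lower/tied (rows sum to
  100); the ranking table labels a site "X lowest"/"X highest" when the
  group's p-criterion holds in both comparisons involving X with X on the
  same side in both. A site can carry one "lowest" and one "highest" label;
  ranking percentages are computed over labels so each group sums to 100.
* **`paired_wilcoxon`** is a generic utility for externally computed
  per-sample statistics (predicted age, cell-type fractions): paired
  Wilcoxon signed-rank per statistic and method pair, Bonferroni-corrected
  over all tests performed.

## Synthetic data generator

The generator emulates the features the analysis relies on:

* **Marginal beta distribution:** per site a component of a three-part
  mixture — mostly-unmethylated Beta(2, 18), intermediate Beta(6, 6),
  mostly-methylated Beta(18, 2) with weights 0.40/0.15/0.45 — chosen to
  reproduce the bimodal shape of array beta-values with a minor
  intermediate shoulder.
* **Biological variation:** per-subject values are the site mean perturbed
  by N(0, subject_sd) on the logit scale (default subject_sd = 0.5, i.e. a
  beta-scale SD around 0.12 at intermediate methylation) — substantially
  larger than technical noise, so subjects, not methods, dominate the
  leading principal components, as in real paired data.
* **Technical noise:** each measurement adds N(0, σ(true)/√2) with
  σ(x) = exp(a + b(x−½)²), defaults a = −3, b = −4 (difference SD ≈ 0.050
  at x = ½ and ≈ 0.018 at the boundaries). The √2 split is a package
  construction: the agreement model only constrains the difference of two
  methods, and equal independent per-method noise reproduces its σ(x)
  exactly.
* **Method effects:** optional global per-method offsets and injected
  regions (a genomic window where one method is shifted by delta), for
  positive controls.
* **Bookkeeping:** values are clamped to [0, 1]; the sample sheet is filled
  with chip positions cycling over a 12-position layout and per-method
  yield/purity metadata drawn from realistic ranges (the salting-out-style
  method is given lower yields and A260/230, mirroring typical laboratory
  observations). Default site annotation is one chromosome at 500-bp
  spacing (adjacent sites fall within a 1000-bp clustering gap); tests use
  explicit annotations with 50-kb gaps to create many small clusters.

Everything is deterministic given the seed (truth and measurement stages
draw from independently spawned generators).

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real arrays: Infinium I/II probe-chemistry
differences, spatial chip artefacts, cell-composition mixtures,
probe cross-reactivity, genotype-driven polymorphic probes, and correlated
noise between neighbouring probes. Clamping to [0, 1] slightly deflates
noise variance near the boundaries relative to the nominal σ(x); with
b = −4 boundary noise is small and the deflation is negligible in practice
(parameter-recovery tests through the full generator stay within ±0.05 on
a and ±0.3 on b), but it is a known bias of the transparent additive-noise
construction, deliberately preferred over logit-scale noise.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use desk-scale sizes chosen to
make the statistical checks sharp: 200,000 points for variance-model
recovery, 100,000 draws for limit coverage, 10,000 sites × 10 subjects for
type-I-error calibration (fraction of raw p < 0.05 within 0.05 ± 0.01),
and 100 seeded null runs of 2,000 sites with 50 bootstraps for region-level
FWER calibration, plus a 20-site injected region (delta = 0.05) as positive
control. Optimizer tolerance 1e-8 on the objective; BH implemented via the
standard step-up routine with NaN-family exclusion; ties in Kruskal–Wallis
handled by the usual tie correction; all random draws flow through
explicitly passed seeds.

## Pipeline and report

`run_pipeline` executes filter → per-pair agreement → PCA screen → per-pair
differential testing from a single validated configuration (unknown keys
rejected), writing one JSON report that embeds every stage output plus
provenance (config hash, package version, seed). The report structure is
published as a JSON schema (`docs/report.schema.json`, generated from the
same pydantic models that validate each report before writing). Timestamps
live in a single header field so reproducibility is testable: two runs with
the same configuration and seed are otherwise byte-identical. A
`MANIFEST.json` records per-stage completion; on failure it carries the
failing stage and error.

## Known limitations

* The variance model is symmetric in x around ½ by construction; real
  difference spreads can be mildly asymmetric.
* The sign-flip bootstrap assumes subject exchangeability under the null;
  strong subject-specific technical artefacts violate it.
* The bump-hunting FWER is granular at 1/n_boot; with 50 bootstraps the
  smallest attainable FWER is 0 and the significance call at 5% rests on
  ≤ 2 exceedances.
* PCA variance fractions are convention-dependent (centring/scaling), so
  only tolerance-level agreement across implementations should be expected.
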