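# methylagree

Method-agreement analysis for paired genome-wide DNA methylation
beta-values.

When the same biological samples are profiled on a methylation array after
different laboratory treatments — e.g. whole-blood DNA isolated with
different extraction methods — the question is whether the treatment shifts
the measured methylation enough to confound downstream epigenome-wide
analyses. `methylagree` implements the statistical toolkit for answering
that question on a paired subjects × methods design:

* **Heteroscedastic Bland–Altman agreement.** Classical limits of agreement
  assume normally distributed differences with constant variance; genome-wide
  beta-value differences satisfy neither (a repeated Shapiro–Wilk subsample
  screen is included). The per-point model is

      d_i = σ(x_i) e_i,   e_i ~ N(0, 1),   σ(x) = exp(a + b (x − ½)²),

  where x_i is the intra-subject average of the two methods' beta-values at
  one CpG and d_i their difference. (a, b) are estimated by non-linear
  minimization of the Gaussian negative log-likelihood and the limits of
  agreement drawn as ±1.96·σ(x). With b < 0 the limits are widest at
  intermediate methylation and narrow toward 0 and 1.
* **Difference-distribution tables**: percentages of CpG sites by absolute
  mean between-method difference, binned at 0.01 resolution.
* **PC–covariate screening**: PCA of the beta matrix (samples as
  observations, site-centred) with per-component Kruskal–Wallis tests
  against categorical technical covariates (method, chip position) and
  two-sided Spearman correlations against numeric ones (DNA yield,
  A260/280, A260/230), Bonferroni-corrected per covariate.
* **Paired differential methylation**: a global paired t-test on per-subject
  mean methylation; per-CpG paired t-tests with Benjamini–Hochberg FDR; and
  a bump-hunting search for differentially methylated regions (maxGap
  clustering, within-cluster loess smoothing, cutoff on the smoothed effect,
  sign-flip bootstrap family-wise error rates), plus directional summaries
  of top hits across three methods.
* **A synthetic-data generator** producing paired multi-method datasets with
  the matching structure: bimodal beta mixtures, between-subject biological
  variation exceeding technical variation, the σ(x) difference noise law,
  optional global method biases and injected method-effect regions — so the
  whole pipeline is testable without any download.

## Worked example

```python
import numpy as np
from methylagree import (SimulationParams, simulate, pairwise_points,
                         fit_variance_model, limits_of_agreement,
                         difference_distribution, global_paired_t,
                         per_site_paired_t, run_pca, pc_association_screen)

params = SimulationParams(n_sites=10_000, n_subjects=10, seed=1)
ds, _ = simulate(params)                       # 10 subjects x 3 methods

pts = pairwise_points(ds, "M", "A")            # 100,000 (x, d) pairs
fit = fit_variance_model(pts)
lo, hi = limits_of_agreement(fit, np.array([0.0, 0.5, 1.0]))
print(f"a = {fit.a:.3f}, b = {fit.b:.3f}, converged = {fit.converged}")
print(f"limits at x = 0, 0.5, 1: ±{hi.round(3)}")

dist = difference_distribution(ds, "M", "A")
print("first three bins (%):", dist.percentages[:3].round(1))

g = global_paired_t(ds, "M", "A")
print(f"global paired t = {g.t:.2f}, p = {g.p_raw:.2f}")

dmp = per_site_paired_t(ds, "M", "A")
print("sites at FDR < 5%:", int((dmp.p_bh < 0.05).sum()))

pca = run_pca(ds)
assoc = pc_association_screen(pca, ds.samples, ["method"])
print("min Bonferroni-adjusted method p over PCs:",
      round(min(r.p_adjusted for r in assoc), 3))
```

prints

```
a = -2.991, b = -4.142, converged = True
limits at x = 0, 0.5, 1: ±[0.035 0.098 0.035]
first three bins (%): [73.3 22.4  3.6]
global paired t = 0.94, p = 0.37
sites at FDR < 5%: 0
min Bonferroni-adjusted method p over PCs: 0.342
```

The generator's truth used a = −3, b = −4, so the fitted variance function
recovers the noise law: the limits of agreement span ±0.098 at intermediate
methylation, narrowing to ±0.035 at the boundaries. Because no method
effect was simulated, 95.7% of sites show a mean difference below 0.02, and
neither the global test, the per-CpG FDR, nor the PC screen flags a method
signal — the pattern expected when extraction method does not confound
methylation measurement.

## Command line

```sh
methylagree simulate --out-dir sim/ --seed 1 --n-sites 10000
methylagree agree --pair M,A --beta sim/simulated_betas.tsv \
    --annotation sim/simulated_annotation.tsv \
    --samplesheet sim/simulated_samples.tsv --out out/ma
methylagree run --config pipeline.yaml --seed 1   # full pipeline + JSON report
```

`methylagree run` writes `report.json` (validated against
`docs/report.schema.json`) and a `MANIFEST.json` marking stage completion;
runs with the same configuration and seed are byte-identical apart from the
header timestamp.

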