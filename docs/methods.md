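# Methods

This note documents the models, the synthetic data they are exercised
on, the numerical choices, and the limits of what the tests show.

## Screen model

A pooled shRNA dropout screen is represented in long format: one row
per (hairpin, cell line, timepoint, replicate) log2-abundance
measurement, annotated with gene and with the line's group (derived
from a primary tumour or a metastasis). Time is coded as the array
index 0/1/2 of the sampling points (baseline and roughly 3 and 6
population doublings); doubling counts are metadata, not the
regression axis. Abundance is log2 by definition of the simulator and
of the model; no normalisation is applied by default.

**Per-trajectory fits.** `fit_hairpin_trend` fits one hairpin's time
course in one line by OLS over all replicates; the intercept is the
initial abundance at t = 0 and the slope is the essentiality score
(log2 change per timepoint unit, negative = dropout).

**Per-line scores.** `line_scores` aggregates a gene's hairpin slopes
within a line by precision weighting (weights 1/Var(slope) from the
OLS fit), falling back to equal weights when residual variances are
unavailable (2-point fits) or zero (exact lines). How per-line scores
should be aggregated from hairpin fits is a genuinely open design
point; precision weighting is the package's documented choice. Missing
gene × line combinations are NaN, never silently zero.

**Differential test.** `differential_essentiality` fits, per gene,
`log2_abundance ~ time + group:time` with hairpin-level random
intercepts and random time slopes, by maximum likelihood (statsmodels
MixedLM, lbfgs, maxiter 200). The group:time coefficient `delta` is
the metastatic − primary slope difference, tested by a Wald test;
p-values are BH-adjusted across all genes in one family. Genes with
fewer than 3 hairpins, and mixed fits that fail or return non-finite
inference, fall back to OLS with fixed per-trajectory intercepts
(one intercept per hairpin × line, since each hairpin's initial
abundance is line-specific). For balanced designs the fixed-effects
interaction equals the difference of the per-group pooled
within-trajectory slopes exactly, which the tests assert at 1e-10.
ML rather than REML is used so per-gene log-likelihoods are
comparable; on the null simulations the Wald test's empirical size is
indistinguishable between the two (~0.05).

**Bimodal dependency split.** For a gene of interest,
`bimodal_dependency_analysis` fits a two-component mixture to the
metastatic lines' scores (at least 4 lines required), assigns lines to
the low (dependent) or high (non-dependent) subpopulation by posterior
responsibility, and reports Welch t-tests for low-vs-high metastatic
and low-metastatic-vs-primary. All-equal scores are flagged unimodal
with no tests.

## Mixture stratification

`fit_gmm_1d` is a self-contained univariate Gaussian-mixture EM:
component means initialised at the (i+0.5)/K data quantiles, 5
restarts (the extra restarts perturb the quantile means), tolerance
1e-6 on the log-likelihood, at most 500 iterations, and a variance
floor of 1e-6 × the data variance to prevent collapse. All restarts
run in one vectorised E/M sweep with converged restarts frozen; the
winning restart's log-likelihood trace is retained and asserted
non-decreasing in tests. K = 1 uses the closed form (sample mean, ML
standard deviation). Components are always reported mean-ascending.

`select_components` votes over candidate K ∈ {1,…,5}: each of the
(default 1000) iterations subsamples 90% of the data without
replacement, fits every K, and scores by BIC (AIC available); the
majority K wins, exact ties going to the smaller K. Consensus
thresholds are the per-boundary means (with sds) over the iterations
whose optimum equals the chosen K. BIC is the package's choice of
"optimal number of Gaussians" — standard for 1-D mixture selection.

`thresholds_from_mixture` places each category boundary where the
weighted densities of adjacent components are equal (posterior 0.5),
solved by bisection between the two means; under extreme weight
imbalance with no crossing, the minimum-ratio point is reported with a
warning. An alternative threshold definition (upper quantile of the
lowest component) was considered and rejected as it ignores the upper
component entirely. `classify` maps values to low / intermediate /
high (or low / high with one threshold); boundary values go to the
upper category.

**Core QC.** `qc_filter_cores` applies the three-step filter: fit a
2-component mixture to artifact area fractions and keep cores strictly
below the boundary of the lowest component; refit on the survivors'
tumor area fractions and keep cores strictly above the boundary; keep
cores with tumor fraction > artifact fraction. Thresholds are refit on
the current survivor set at each step, matching the narrated order of
the procedure. `fixed` mode applies supplied thresholds (e.g. 0.07 and
0.3) without refitting and is verified against a brute-force row
filter on 1000 random tables.

## Association statistics

`chisq_test` computes the Pearson statistic with margin-derived
expectations. Simulated p-values draw replicate tables conditional on
both observed margins (Patefield's algorithm via scipy
`random_table`) and use the add-one estimator
p = (1 + #{replicate ≥ observed}) / (1 + R), so p is never exactly 0.
Note the margin-conditional null is discrete: for small 2×2 tables the
simulated p converges to the hypergeometric tail probability, which
can differ visibly from the asymptotic chi-squared p (0.0194 vs
0.0098 on the worked [[10,20],[20,10]] table); the tests check the
simulated p against the enumerated conditional oracle and check
convergence to the asymptotic p on a dense-support large-count table.

`bh_adjust` (statsmodels step-up), `welch_t` (Satterthwaite df in
closed form) and `crosstab_proportions` (within-row proportions of a
second marker's strata) are thin, validated wrappers. Stage
associations collapse pT stages to early (1–2) vs late (3–4); optional
category-collapse maps (e.g. intermediate+high vs low) are applied
before testing, and BH runs across the declared family of per-marker
comparisons — the family is a configuration input because there is no
single canonical choice.

`concordant_de_filter` runs a per-gene one-way ANOVA across the
pair × site condition groups, BH at FDR 0.05, then keeps genes whose
metastatic-vs-primary change reaches the fold cutoff in the same
direction in *every* patient pair; fold changes are computed on the
linear scale from log2 data (2^|Δlog2|). This deliberately simplifies
a Tukey-HSD post-hoc step to the ANOVA+BH+fold chain.
`competitive_ratio` divides the per-timepoint A/B cell-count ratio by
the scrambled-control ratio, so drift shared with the control cancels.

## Synthetic data

`simulate_screen` draws hairpin counts per gene from a Poisson with
mean 5 truncated at ≥ 1 (the screens average 5 hairpins/gene but the
count is not fixed), a per-hairpin baseline ~ N(9, 1) log2 units
shared across lines, and observation noise N(0, 0.3) per measurement
at timepoints 0/1/2 with 3 replicates — dropout of an essential
hairpin is an exponential decay of abundance, i.e. linear in log2.
Defaults use 3 primary + 3 metastatic lines (the matched-pairs
geometry) with half the metastatic lines dependent on the designated
differential genes (the bimodal split); globally essential genes drop
out everywhere (slope −1), neutral genes are flat. σ = 0.3 log2 units
gives per-hairpin slope SEs of ~0.12, comfortably separating a
delta of −1 while leaving the null test non-trivial.

`simulate_tma` draws artifact and tumor area fractions and per-marker
positive-cell fractions from configured 2–3-component mixtures on
[0,1], truncating by resampling rather than clipping so no probability
atoms appear at the boundaries and EM still sees mixture-shaped data.
The latent class of a designated stage marker sets the log-odds of a
late pT stage (default spacing 1.1 ≈ ln 3 between adjacent classes);
within early/late the two constituent stages are equally likely.
`simulate_expression` shifts designated genes by log2(fold)
consistently (or per-pair, for discordance tests) across patient
pairs, with 3 replicate samples per pair and site because the
downstream ANOVA needs within-group replication.

One global seed expands via `SeedSequence.spawn` into independent
per-stream sub-seeds, so adding a marker or gene does not perturb the
other streams; every generator is a pure function of (config, seed).

What the simulators do *not* emulate: array probe chemistry and
saturation, hairpin off-target structure, correlated noise across
timepoints, batch effects, inter-core spatial correlation on a TMA
slide, and stage misclassification. Passing tests therefore
demonstrate correctness of the estimators under the assumed
statistical structure, not robustness to those real-data artifacts.

## Problem sizes and tolerances

The test suite and acceptance script run at desk scale, chosen so each
block completes in seconds to a few minutes on one core: 200 genes for
recovery checks (exactness asserted at 1e-8 on zero noise), 500 genes
for the null calibration (size within [0.03, 0.07], a ±2 binomial-sd
band around 0.05), 20 seeded runs for ranking and power checks, 200
resampling iterations for component-number votes, and n = 2000 per
dataset for threshold recovery. The analytic threshold comparison
averages 10 independent replicate fits because a single fitted
threshold has a sampling sd of ~0.07 at n = 2000 (verified against
scikit-learn on identical data); the mean estimates the population
quantity at SE ≈ 0.02. Monte-Carlo p-value checks use 3 Monte-Carlo
standard errors around enumerated oracles.

## Known limitations

- The mixed model assumes Gaussian noise and a common residual
  variance per gene; heavy-tailed screen noise would call for robust
  or moderated variants.
- Wald inference on the interaction is asymptotic in the number of
  measurements per gene (~270 at defaults); very small designs should
  use the permutation calibration demonstrated in the tests.
- EM with an overspecified K (4–5 on 2–3-population data) routinely
  hits the 500-iteration cap without formal convergence; BIC still
  penalises such fits correctly, but their parameters should not be
  interpreted.
- The threshold between heavily imbalanced components may not exist as
  a density crossing; the reported minimum-ratio point is flagged and
  should be reviewed.
- No survival analysis, enrichment analysis, image segmentation or
  upstream array preprocessing is included by design.
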