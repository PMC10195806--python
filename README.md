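# metscreen

Differential gene-essentiality analysis for pooled shRNA dropout
screens on matched primary/metastatic cancer cell lines, and
Gaussian-mixture stratification of tissue-microarray (TMA) biomarker
fractions with stage-association statistics. Everything runs
end-to-end on seeded synthetic data with the statistical structure the
real assays produce, so the full pipeline is testable without any
external downloads.

The package is aimed at computational biologists analysing loss-of-
function screens (which genes does a tumour subpopulation depend on?)
and immunohistochemistry cohorts (does marker expression stratify with
pathological stage?).

## Models

**Essentiality scores.** In a pooled dropout screen each gene is
targeted by ~5 short-hairpin RNAs; the abundance of every hairpin is
measured (log2 scale) at timepoints t = 0, 1, 2 in replicate. A
hairpin's time course is modelled as a line: the intercept is its
initial abundance and the slope — the *essentiality score* — is its
dropout rate (negative = depleting = essential). Differential
essentiality between line groups is the group × time interaction of a
per-gene hierarchical model

```
log2_abundance ~ time + group:time   + per-hairpin random intercepts and slopes
```

fitted by maximum likelihood (statsmodels `MixedLM`), with an OLS
fallback using fixed per-trajectory intercepts for genes with few
hairpins or failed fits. The interaction coefficient `delta` is the
metastatic − primary slope difference, tested per gene by a Wald test
and Benjamini–Hochberg adjusted across genes.

**Mixture stratification.** Per-core marker fractions (fraction of
marker-positive cells) are modelled as 1-D Gaussian mixtures fitted by
EM (quantile initialisation, 5 restarts, variance floor). The number
of components is chosen by a resampling vote: 1000 iterations of 90%
subsampling, each scored by BIC; thresholds between adjacent
components are the points where weighted component densities are equal
(posterior responsibility 0.5), averaged over the qualifying
iterations. Cores are then classified low / intermediate / high, and
strata are tested against early (pT1–2) vs late (pT3–4) stage with
Pearson chi-squared tests using Monte-Carlo p-values conditional on
both margins (Patefield sampling, 2000 replicates), BH-adjusted across
markers. The same mixture machinery drives the three-step core QC
filter (artifact-fraction threshold, tumor-fraction threshold,
tumor > artifact).

## Worked example

`examples/01_screen_differential_essentiality.py` simulates a
60-gene screen in which gene `g0020` is essential only in metastatic
lines, and prints:

```
top 5 genes by interaction p-value:
gene_id  slope_primary  slope_metastatic    delta  p_value  q_value
  g0020       -0.01417           -0.9971   -0.983        0        0
  g0057       -0.04941           0.04286  0.09227 0.003132  0.09397
  g0047        -0.9837             -1.02 -0.03604   0.0824   0.9421
```

`g0020` is recovered with delta ≈ −1: its hairpins drop out one extra
log2 unit per timepoint in metastatic lines. Note `g0047`, a globally
essential gene (both slopes ≈ −1), is *not* called differential.

`examples/03_tma_stratification.py` runs the full TMA chain and prints:

```
QC: 300 cores -> 208 (artifact < 0.078) -> 155 (tumor > 0.289) -> 155 (tumor > artifact)
component vote: {2: 100} -> K = 2
consensus threshold(s): [0.343]
chi-squared = 34.27, simulated p = 0.0004998
```

i.e. the resampled BIC vote selects two expression populations, the
consensus boundary sits at a positive-cell fraction of 0.343, and
high-expressing cores are strongly enriched in late-stage tumors.

The other examples cover the bimodal dependency split
(`02_bimodal_dependency.py`) and the closed-form statistics toolbox
(`04_statistics_toolbox.py`). A thin CLI mirrors the chains:
`metscreen simulate-screen | simulate-tma | fit-screen | tma-qc |
tma-strata | associate | report | codon`.

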