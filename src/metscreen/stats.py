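"""Stage-association and group-comparison statistics.

Covers the downstream statistics of the stratification workflow:
Pearson chi-squared tests of stage (early pT1-2 vs late pT3-4) against
expression stratum, with Monte-Carlo p-values computed under fixed
margins (Patefield sampling, 2000 replicates by default),
Benjamini-Hochberg adjustment across a declared family of comparisons,
Welch two-sample t-tests, within-stratum crosstab proportions, the
concordant differential-expression filter (ANOVA + BH + per-pair fold
rule) and normalisation of competitive co-culture ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .mixture import StrataAssignment


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float | None = None
    method: str = ""
    n_replicates: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _as_counts(table: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2x2")
    if not np.issubdtype(arr.dtype, np.number):
        raise ValidationError("contingency table must be numeric")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be nonnegative integers")
    return np.round(arr).astype(np.int64)


def _pearson_stat(obs: np.ndarray) -> float:
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    return float(((obs - expected) ** 2 / expected).sum())


def chisq_test(
    table: pd.DataFrame | np.ndarray,
    simulate: bool = False,
    n_replicates: int = 2000,
    seed: int | None = None,
) -> TestResult:
    """Pearson chi-squared test of independence.

    With ``simulate=True`` the p-value is Monte-Carlo: replicate tables
    are drawn conditional on both observed margins (Patefield's
    algorithm) and p = (1 + #{replicate statistic >= observed}) /
    (1 + n_replicates), so it is never exactly zero.
    """
    obs = _as_counts(table)
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValidationError("contingency table has a zero margin")
    stat = _pearson_stat(obs)
    if not simulate:
        df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
        p = float(sps.chi2.sf(stat, df))
        return TestResult(stat, max(p, np.finfo(float).tiny), df=df, method="pearson")
    rng = np.random.default_rng(seed)
    sampler = sps.random_table(obs.sum(axis=1), obs.sum(axis=0), seed=rng)
    reps = sampler.rvs(n_replicates)  # Patefield
    row = reps.sum(axis=2, keepdims=True)
    col = reps.sum(axis=1, keepdims=True)
    expected = row * col / obs.sum()
    stats_rep = ((reps - expected) ** 2 / expected).sum(axis=(1, 2))
    n_ge = int((stats_rep >= stat - 1e-12).sum())
    p = (1 + n_ge) / (1 + n_replicates)
    return TestResult(
        stat, p, df=None, method="pearson-montecarlo", n_replicates=n_replicates, seed=seed
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Welch two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("each sample needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, df=np.nan, method="welch-degenerate")
        raise DegenerateDataError("zero variance in both samples with unequal means")
    sx, sy = vx / len(x), vy / len(y)
    t = float((x.mean() - y.mean()) / np.sqrt(sx + sy))
    df = float((sx + sy) ** 2 / (sx**2 / (len(x) - 1) + sy**2 / (len(y) - 1)))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(t, p, df=df, method="welch")


@dataclass
class CrosstabResult:
    counts: pd.DataFrame
    proportions: pd.DataFrame  # rows (A categories) sum to 1


def crosstab_proportions(
    strata_a: StrataAssignment, strata_b: StrataAssignment
) -> CrosstabResult:
    """Within each category of marker A, the proportions of marker B categories."""
    shared = strata_a.categories.index.intersection(strata_b.categories.index)
    if len(shared) == 0:
        raise ValidationError("strata assignments share no sample ids")
    a = strata_a.categories.loc[shared]
    b = strata_b.categories.loc[shared]
    counts = pd.crosstab(a, b, dropna=False)
    present = counts.sum(axis=1) > 0
    if not present.all():
        warnings.warn(
            f"empty categories omitted: {counts.index[~present].tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    counts = counts[present]
    props = counts.div(counts.sum(axis=1), axis=0)
    return CrosstabResult(counts=counts, proportions=props)


@dataclass
class DEFilterResult:
    """Genes concordantly differential across all patient pairs."""

    up_gene_ids: list[str]
    down_gene_ids: list[str]
    fold_changes: pd.DataFrame  # genes x pairs, signed log2 fold (met - pri)
    q_values: pd.Series


def concordant_de_filter(
    expr_matrix: pd.DataFrame,
    pair_design: pd.DataFrame,
    fold: float = 1.5,
    fdr: float = 0.05,
) -> DEFilterResult:
    """Concordant differential-expression filter across matched pairs.

    ``expr_matrix`` is genes x samples on the log2 scale; ``pair_design``
    maps each sample (index) to its patient ``pair`` and ``site``
    (primary/metastatic). Per gene, a one-way ANOVA across the
    pair-by-site condition groups is BH-adjusted at ``fdr``; survivors
    are kept only if the metastatic-vs-primary change reaches the fold
    cutoff in the same direction in every pair (fold change on the
    linear scale, 2^|delta log2|).
    """
    if not {"pair", "site"} <= set(pair_design.columns):
        raise ValidationError("pair_design needs 'pair' and 'site' columns")
    missing = [s for s in pair_design.index if s not in expr_matrix.columns]
    if missing:
        raise ValidationError(f"design samples absent from matrix: {missing[:5]}")
    pairs = sorted(pair_design["pair"].unique())
    if len(pairs) < 2:
        raise ValidationError("need >=2 patient pairs")
    groups = {
        key: list(sub.index)
        for key, sub in pair_design.groupby(["pair", "site"], sort=True)
    }
    group_arrays = [expr_matrix[cols].to_numpy(float) for cols in groups.values()]
    if min(a.shape[1] for a in group_arrays) < 2:
        raise ValidationError("each pair-by-site group needs >=2 replicate samples")
    with np.errstate(invalid="ignore"):
        _, pvals = sps.f_oneway(*group_arrays, axis=1)
    pvals = np.nan_to_num(pvals, nan=1.0)  # zero-variance genes are null
    q = pd.Series(bh_adjust(pvals), index=expr_matrix.index, name="q_value")

    log2fold = float(np.log2(fold))
    fc = pd.DataFrame(index=expr_matrix.index, columns=pairs, dtype=float)
    for pair in pairs:
        met = expr_matrix[groups[(pair, "metastatic")]].mean(axis=1)
        pri = expr_matrix[groups[(pair, "primary")]].mean(axis=1)
        fc[pair] = met - pri
    passed = q < fdr
    up = passed & (fc >= log2fold).all(axis=1)
    down = passed & (fc <= -log2fold).all(axis=1)
    return DEFilterResult(
        up_gene_ids=expr_matrix.index[up].tolist(),
        down_gene_ids=expr_matrix.index[down].tolist(),
        fold_changes=fc,
        q_values=q,
    )


def competitive_ratio(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    control_ratio: Sequence[float],
) -> np.ndarray:
    """Normalised competitive co-culture ratio per timepoint.

    Returns (A/B) divided by the scrambled-control ratio at the same
    timepoint, so drift shared with the control cancels. Timepoints
    with a zero denominator are NaN with a warning.
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    c = np.asarray(control_ratio, float)
    if not (len(a) == len(b) == len(c)):
        raise ValidationError("series must share timepoints")
    denom = b * c
    bad = denom == 0
    if bad.any():
        warnings.warn(
            f"zero denominator at timepoints {np.flatnonzero(bad).tolist()}",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a / b) / c
    out[bad] = np.nan
    return out
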