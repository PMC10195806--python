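"""Essentiality scoring from pooled shRNA dropout-screen time courses.

A pooled loss-of-function screen measures the log2 abundance of every
hairpin in the library at successive timepoints; hairpins targeting
essential genes drop out of the population, so the slope of the
log-abundance time course — the *essentiality score* — is negative for
essential genes. Differential essentiality between sample groups
(here, cell lines derived from primary tumours vs metastases) is the
group x time interaction of a per-gene hierarchical regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ModelError,
    ValidationError,
)

SCREEN_COLUMNS = [
    "hairpin_id",
    "gene_id",
    "line_id",
    "group",
    "timepoint",
    "replicate",
    "log2_abundance",
]

GROUPS = ("primary", "metastatic")


@dataclass
class ScreenDataset:
    """Long-format pooled-screen abundance table.

    One row per (hairpin, line, timepoint, replicate) measurement, each
    annotated with its gene and the line's primary/metastatic group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SCREEN_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"screen table missing columns: {missing}")
        t = self.table
        if not np.isfinite(t["log2_abundance"].to_numpy(float)).all():
            raise ValidationError("log2_abundance contains non-finite values")
        bad_group = set(t["group"].unique()) - set(GROUPS)
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        n_genes = t.groupby("hairpin_id")["gene_id"].nunique()
        if (n_genes > 1).any():
            offenders = n_genes[n_genes > 1].index.tolist()[:5]
            raise ValidationError(f"hairpins mapped to >1 gene: {offenders}")
        n_t = t.groupby("line_id")["timepoint"].nunique()
        if (n_t < 2).any():
            raise ValidationError(
                f"lines with <2 distinct timepoints: {n_t[n_t < 2].index.tolist()}"
            )

    @property
    def genes(self) -> list[str]:
        return sorted(self.table["gene_id"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.table["line_id"].unique())

    def grouping(self) -> dict[str, str]:
        """Mapping line_id -> primary/metastatic derived from the table."""
        g = self.table.drop_duplicates("line_id").set_index("line_id")["group"]
        return g.to_dict()

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScreenDataset":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))


@dataclass
class TrajectoryFit:
    """OLS line through one hairpin's time course in one cell line."""

    hairpin_id: str
    line_id: str
    intercept: float  # log2 abundance at timepoint 0
    slope: float  # log2 change per timepoint unit; negative = dropout
    residual_sd: float
    n_points: int


@dataclass
class EssentialityRecord:
    """Per-gene differential-essentiality result.

    ``delta`` is the metastatic-minus-primary difference in dropout
    slope (the group x time coefficient); a negative delta means the
    gene is more essential in metastasis-derived lines.
    """

    gene_id: str
    slope_primary: float
    slope_metastatic: float
    delta: float
    se_delta: float
    p_value: float
    q_value: float = np.nan
    method: str = "fixed"
    converged: bool = True


@dataclass
class LineScoreMatrix:
    """Gene x line matrix of per-line essentiality scores (slopes)."""

    scores: pd.DataFrame  # genes x lines, NaN = missing combination
    groups: dict[str, str] = field(default_factory=dict)

    def missing_mask(self) -> pd.DataFrame:
        return self.scores.isna()

    def to_csv(self, path: str | Path) -> None:
        self.scores.to_csv(path)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Closed-form OLS of y on t: (intercept, slope, residual_sd, var_slope)."""
    n = len(t)
    tbar, ybar = t.mean(), y.mean()
    sxx = float(((t - tbar) ** 2).sum())
    if sxx == 0:
        raise InsufficientDataError("need >=2 distinct timepoints")
    slope = float(((t - tbar) * (y - ybar)).sum() / sxx)
    intercept = float(ybar - slope * tbar)
    resid = y - (intercept + slope * t)
    if n > 2:
        sigma2 = float((resid**2).sum() / (n - 2))
    else:
        sigma2 = np.nan
    residual_sd = np.sqrt(sigma2) if n > 2 else np.nan
    var_slope = sigma2 / sxx if n > 2 else np.nan
    return intercept, slope, residual_sd, var_slope


def fit_hairpin_trend(
    dataset: ScreenDataset, hairpin_id: str, line_id: str
) -> TrajectoryFit:
    """Fit one hairpin's abundance time course in one line by OLS.

    The intercept is the fitted log2 abundance at timepoint 0 (the
    initial abundance); the slope is the dropout rate.
    """
    sub = dataset.table
    sub = sub[(sub["hairpin_id"] == hairpin_id) & (sub["line_id"] == line_id)]
    if sub["timepoint"].nunique() < 2:
        raise InsufficientDataError(
            f"hairpin {hairpin_id!r} in line {line_id!r} has <2 distinct timepoints"
        )
    t = sub["timepoint"].to_numpy(float)
    y = sub["log2_abundance"].to_numpy(float)
    intercept, slope, residual_sd, _ = _ols_line(t, y)
    return TrajectoryFit(hairpin_id, line_id, intercept, slope, residual_sd, len(t))


def _hairpin_slopes(table: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, line, hairpin) OLS slope and slope variance, vectorised."""
    rows = []
    for (gene, line, hp), sub in table.groupby(
        ["gene_id", "line_id", "hairpin_id"], sort=True
    ):
        t = sub["timepoint"].to_numpy(float)
        if len(np.unique(t)) < 2:
            continue
        y = sub["log2_abundance"].to_numpy(float)
        _, slope, _, var_slope = _ols_line(t, y)
        rows.append((gene, line, hp, slope, var_slope))
    return pd.DataFrame(
        rows, columns=["gene_id", "line_id", "hairpin_id", "slope", "var_slope"]
    )


def line_scores(dataset: ScreenDataset) -> LineScoreMatrix:
    """Per-(gene, line) essentiality score.

    The score is the precision-weighted mean of the gene's hairpin
    slopes in that line (weights 1/variance of the slope estimate);
    equal weights are used when slope variances are unavailable or
    degenerate (e.g. 2-point fits or zero residuals). Gene/line
    combinations absent from the dataset are NaN, never silently zero.
    """
    hp = _hairpin_slopes(dataset.table)
    if hp.empty:
        mat = pd.DataFrame(index=dataset.genes, columns=dataset.lines, dtype=float)
        return LineScoreMatrix(scores=mat, groups=dataset.grouping())

    def _score(sub: pd.DataFrame) -> float:
        s = sub["slope"].to_numpy(float)
        v = sub["var_slope"].to_numpy(float)
        ok = np.isfinite(v) & (v > 0)
        if ok.all() and len(s) > 0:
            w = 1.0 / v
            return float((w * s).sum() / w.sum())
        return float(s.mean())

    scored = hp.groupby(["gene_id", "line_id"]).apply(_score, include_groups=False)
    mat = scored.unstack("line_id")
    mat = mat.reindex(index=dataset.genes, columns=dataset.lines)
    return LineScoreMatrix(scores=mat, groups=dataset.grouping())


def _fit_gene_fixed(df: pd.DataFrame) -> tuple[float, float, float, float]:
    """OLS with per-trajectory fixed intercepts: y ~ C(traj) + t + t:group.

    A trajectory is one hairpin in one line; its intercept is that
    hairpin's initial abundance in that line.
    """
    if df["traj"].nunique() > 1:
        formula = "log2_abundance ~ C(traj) + timepoint + timepoint:grp"
    else:
        formula = "log2_abundance ~ timepoint + timepoint:grp"
    fit = smf.ols(formula, df).fit()
    slope_primary = float(fit.params["timepoint"])
    delta = float(fit.params["timepoint:grp"])
    se = float(fit.bse["timepoint:grp"])
    p = float(fit.pvalues["timepoint:grp"])
    return slope_primary, delta, se, p


def _fit_gene_mixed(df: pd.DataFrame) -> tuple[float, float, float, float, bool]:
    """Mixed model with hairpin-level random intercepts and time slopes."""
    md = smf.mixedlm(
        "log2_abundance ~ timepoint + timepoint:grp",
        df,
        groups=df["hairpin_id"],
        re_formula="~timepoint",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)  # singular RE covariance
        fit = md.fit(reml=False, method="lbfgs", maxiter=200)
    converged = bool(getattr(fit, "converged", True))
    slope_primary = float(fit.params["timepoint"])
    delta = float(fit.params["timepoint:grp"])
    se = float(fit.bse["timepoint:grp"])
    p = float(fit.pvalues["timepoint:grp"])
    if not np.isfinite(p) or not np.isfinite(se):
        raise ModelError("mixed fit produced non-finite inference")
    return slope_primary, delta, se, p, converged


def differential_essentiality(
    dataset: ScreenDataset,
    grouping: Mapping[str, str] | None = None,
    method: Literal["auto", "mixed", "fixed"] = "auto",
) -> pd.DataFrame:
    """Test each gene for a primary-vs-metastatic difference in dropout rate.

    Under ``method='mixed'``/``'auto'`` each gene is fitted as
    ``log2_abundance ~ time + group:time`` with hairpin-level random
    intercepts and random time slopes. Genes with <3 hairpins, or mixed
    fits that fail, fall back to OLS with fixed per-trajectory
    intercepts (one hairpin in one line). The group:time
    coefficient is the differential-essentiality delta (metastatic -
    primary slope), tested by a Wald test and BH-adjusted across genes.

    Returns a DataFrame with one row per gene: slope_primary,
    slope_metastatic, delta, se_delta, p_value, q_value, method,
    converged — sorted by p_value (volcano-ready).
    """
    table = dataset.table
    if grouping is None:
        grouping = dataset.grouping()
    groups_present = {grouping[l] for l in table["line_id"].unique()}
    if len(groups_present) < 2:
        raise ModelError(
            "differential test needs lines in both groups; "
            f"only {sorted(groups_present)} present"
        )
    if table["timepoint"].nunique() < 2:
        raise ModelError("differential test needs >=2 distinct timepoints")

    work = table.copy()
    work["grp"] = work["line_id"].map(grouping).map({"primary": 0, "metastatic": 1})
    work["traj"] = work["hairpin_id"] + "::" + work["line_id"]

    records: list[EssentialityRecord] = []
    for gene, df in work.groupby("gene_id", sort=True):
        n_hp = df["hairpin_id"].nunique()
        use_mixed = method == "mixed" or (method == "auto" and n_hp >= 3)
        converged = True
        used = "fixed"
        if use_mixed:
            try:
                slope_p, delta, se, p, converged = _fit_gene_mixed(df)
                used = "mixed"
            except Exception:
                slope_p, delta, se, p = _fit_gene_fixed(df)
                used = "fixed-fallback"
                converged = False
        else:
            slope_p, delta, se, p = _fit_gene_fixed(df)
        records.append(
            EssentialityRecord(
                gene_id=gene,
                slope_primary=slope_p,
                slope_metastatic=slope_p + delta,
                delta=delta,
                se_delta=se,
                p_value=p,
                method=used,
                converged=converged,
            )
        )

    out = pd.DataFrame([r.__dict__ for r in records])
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p_value", ignore_index=True)


@dataclass
class BimodalSplit:
    """Two-group split of per-line scores for one gene, with Welch tests."""

    bimodal: bool
    low_lines: list[str]
    high_lines: list[str]
    model: "object | None"  # MixtureModel1D when bimodal
    welch_low_vs_high: "object | None"  # TestResult
    welch_low_vs_primary: "object | None"


def bimodal_dependency_analysis(
    scores: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str],
) -> BimodalSplit:
    """Split metastatic lines into dependent/non-dependent subpopulations.

    Fits a two-component Gaussian mixture to the metastatic lines'
    essentiality scores for one gene and assigns each line to the low
    (dependent) or high (non-dependent) subpopulation by posterior
    responsibility. Returns Welch t-tests comparing the two metastatic
    subpopulations and the low subpopulation against primary lines.
    """
    from .mixture import fit_gmm_1d
    from .stats import welch_t

    s = pd.Series(scores, dtype=float).dropna()
    met = s[[l for l in s.index if groups.get(l) == "metastatic"]]
    pri = s[[l for l in s.index if groups.get(l) == "primary"]]
    if len(met) < 4:
        raise InsufficientDataError(
            f"need >=4 metastatic lines with scores, got {len(met)}"
        )
    vals = met.to_numpy(float)
    if np.ptp(vals) == 0:
        return BimodalSplit(False, [], met.index.tolist(), None, None, None)
    model = fit_gmm_1d(vals, K=2, seed=0)
    # posterior responsibility of the lower-mean component
    resp = model.responsibilities(vals)
    low_mask = resp[:, 0] > 0.5
    low = met.index[low_mask].tolist()
    high = met.index[~low_mask].tolist()
    w_lh = w_lp = None
    if len(low) >= 2 and len(high) >= 2:
        try:
            w_lh = welch_t(met[low].to_numpy(), met[high].to_numpy())
        except DegenerateDataError:
            w_lh = None
    if len(low) >= 2 and len(pri) >= 2:
        try:
            w_lp = welch_t(met[low].to_numpy(), pri.to_numpy())
        except DegenerateDataError:
            w_lp = None
    return BimodalSplit(True, low, high, model, w_lh, w_lp)
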