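"""1-D Gaussian-mixture EM, component-number selection and stratification.

The stratification workflow fits a univariate Gaussian mixture to a
biomarker distribution (fraction of marker-positive cells per tissue
core), chooses the number of components by repeated 90% subsampling
with a BIC vote, converts the consensus fit into category boundaries at
the points where adjacent weighted component densities are equal
(posterior responsibility 0.5), and assigns each core to a low /
intermediate / high stratum. The same mixture machinery drives the
three-step tissue-microarray core QC filter on artifact and tumor area
fractions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .errors import (
    DegenerateDataError,
    InsufficientDataError,
    ValidationError,
)

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MixtureModel1D:
    """Fitted univariate Gaussian mixture, components sorted by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def K(self) -> int:
        return len(self.means)

    def logpdf_components(self, x: np.ndarray) -> np.ndarray:
        """n x K matrix of log(weight_k * N(x | mean_k, sd_k))."""
        x = np.asarray(x, float)[:, None]
        return (
            np.log(self.weights)[None, :]
            - 0.5 * _LOG_2PI
            - np.log(self.sds)[None, :]
            - 0.5 * ((x - self.means[None, :]) / self.sds[None, :]) ** 2
        )

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        lp = self.logpdf_components(np.asarray(x, float))
        lp -= lp.max(axis=1, keepdims=True)
        r = np.exp(lp)
        return r / r.sum(axis=1, keepdims=True)

    def bic(self, n: int) -> float:
        n_params = 3 * self.K - 1
        return -2.0 * self.loglik + n_params * np.log(n)

    def aic(self) -> float:
        return -2.0 * self.loglik + 2 * (3 * self.K - 1)


def _em_restarts(
    x: np.ndarray,
    means0: np.ndarray,  # (R, K) initial means, one row per restart
    sd0: float,
    tol: float,
    max_iter: int,
    var_floor: float,
) -> MixtureModel1D:
    """Run EM for all restarts simultaneously; return the best fit.

    All restarts share one vectorised E/M sweep (arrays n x R x K); a
    restart whose log-likelihood change drops below ``tol`` is frozen.
    The log-likelihood trace of the winning restart is kept so EM
    monotonicity can be asserted.
    """
    n = len(x)
    R, K = means0.shape
    means = means0.copy()
    sds = np.full((R, K), sd0)
    weights = np.full((R, K), 1.0 / K)
    ll = np.full(R, -np.inf)
    n_iter = np.zeros(R, dtype=int)
    active = np.ones(R, dtype=bool)
    traces: list[np.ndarray] = []
    xc = x[:, None, None]  # n x 1 x 1
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        lp = (
            np.log(weights[idx])[None, :, :]
            - 0.5 * _LOG_2PI
            - np.log(sds[idx])[None, :, :]
            - 0.5 * ((xc - means[idx][None, :, :]) / sds[idx][None, :, :]) ** 2
        )  # n x |idx| x K
        m = lp.max(axis=2, keepdims=True)
        e = np.exp(lp - m)  # one exp pass; reused for lse and resp
        esum = e.sum(axis=2)
        lse = m[..., 0] + np.log(esum)  # n x |idx|
        ll_new = lse.sum(axis=0)
        done = np.abs(ll_new - ll[idx]) < tol
        ll[idx] = ll_new
        n_iter[idx] = it
        traces.append(ll.copy())
        active[idx[done]] = False
        live = ~done
        if not live.any():
            break
        resp = e[:, live, :] / esum[:, live, None]
        sub = idx[live]
        nk = np.maximum(resp.sum(axis=0), 1e-300)  # live x K
        weights[sub] = nk / n
        means[sub] = (resp * x[:, None, None]).sum(axis=0) / nk
        var = (resp * (x[:, None, None] - means[sub][None, :, :]) ** 2).sum(axis=0) / nk
        sds[sub] = np.sqrt(np.maximum(var, var_floor))
    best = int(np.argmax(ll))
    order = np.argsort(means[best])
    trace = np.array([t[best] for t in traces])
    trace = trace[np.isfinite(trace)]
    return MixtureModel1D(
        weights=weights[best][order],
        means=means[best][order],
        sds=sds[best][order],
        loglik=float(ll[best]),
        converged=not active[best],
        n_iter=int(n_iter[best]),
        loglik_trace=trace,
    )


def fit_gmm_1d(
    values: Sequence[float],
    K: int,
    init: Literal["quantile"] = "quantile",
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 5,
    variance_floor: float | None = None,
    seed: int | None = None,
) -> MixtureModel1D:
    """Fit a K-component univariate Gaussian mixture by EM.

    Initialisation places component means at the ((i+0.5)/K) quantiles
    of the data; additional restarts perturb those means. The
    best-log-likelihood fit over restarts is returned with components
    sorted by mean. The component variances are floored at
    ``variance_floor`` (default 1e-6 x the data variance) to prevent
    collapse onto single points.
    """
    x = np.asarray(values, float).ravel()
    if K < 1:
        raise ValidationError(f"K must be >=1, got {K}")
    if len(x) < K:
        raise InsufficientDataError(f"need n >= K, got n={len(x)}, K={K}")
    if not np.isfinite(x).all():
        raise ValidationError("values contain non-finite entries")
    data_var = float(x.var())
    if np.ptp(x) == 0.0 and K > 1:
        raise DegenerateDataError("all values identical; cannot fit K>1 mixture")
    if K == 1:
        mu = float(x.mean())
        sd = float(x.std())  # ML divisor n
        floor = variance_floor if variance_floor is not None else 1e-6 * max(data_var, 1e-300)
        sd = max(sd, np.sqrt(floor))
        ll = float(norm.logpdf(x, mu, sd).sum())
        return MixtureModel1D(
            weights=np.array([1.0]),
            means=np.array([mu]),
            sds=np.array([sd]),
            loglik=ll,
            converged=True,
            n_iter=0,
            loglik_trace=np.array([ll]),
        )
    var_floor = variance_floor if variance_floor is not None else 1e-6 * data_var
    rng = np.random.default_rng(seed)
    q = (np.arange(K) + 0.5) / K
    base_means = np.quantile(x, q)
    base_sd = max(x.std() / K, np.sqrt(var_floor))
    means0 = np.tile(base_means, (n_restarts, 1))
    if n_restarts > 1:
        means0[1:] += rng.normal(0, x.std() / K, size=(n_restarts - 1, K))
    return _em_restarts(x, means0, base_sd, tol, max_iter, var_floor)


def thresholds_from_mixture(model: MixtureModel1D) -> list[float]:
    """Category boundaries between adjacent components.

    Each boundary is the point between two adjacent (mean-ordered)
    components where their weighted densities are equal, i.e. where the
    posterior responsibility crosses 0.5; found by bisection between
    the two means. With K=1 the list is empty. If extreme weight
    imbalance leaves no crossing between the means, the point
    minimising the absolute log weighted-density ratio is reported with
    a warning.
    """
    out: list[float] = []
    for i in range(model.K - 1):
        w1, m1, s1 = model.weights[i], model.means[i], model.sds[i]
        w2, m2, s2 = model.weights[i + 1], model.means[i + 1], model.sds[i + 1]

        def logratio(t: float) -> float:
            return (np.log(w1) + norm.logpdf(t, m1, s1)) - (
                np.log(w2) + norm.logpdf(t, m2, s2)
            )

        if m2 - m1 <= 0:
            out.append(float((m1 + m2) / 2))
            continue
        a, b = float(m1), float(m2)
        fa, fb = logratio(a), logratio(b)
        if fa > 0 and fb < 0:
            out.append(float(brentq(logratio, a, b, xtol=1e-12)))
        else:
            grid = np.linspace(a, b, 2001)
            vals = np.abs([logratio(t) for t in grid])
            t_star = float(grid[int(np.argmin(vals))])
            warnings.warn(
                "no weighted-density crossing between component means "
                f"{m1:.4g} and {m2:.4g}; reporting minimum-ratio point",
                RuntimeWarning,
                stacklevel=2,
            )
            out.append(t_star)
    return out


def majority_vote(votes: Mapping[int, int]) -> int:
    """Winning component count; exact ties go to the smaller K (parsimony)."""
    if not votes:
        raise ValidationError("empty vote map")
    top = max(votes.values())
    return min(k for k, v in votes.items() if v == top)


@dataclass
class ResampleSelection:
    """Vote over component numbers from repeated subsample refits."""

    votes: dict[int, int]
    chosen_K: int
    qualifying_iterations: int
    consensus_thresholds: list[tuple[float, float]]  # (mean, sd) per boundary

    @property
    def n_iterations(self) -> int:
        return sum(self.votes.values())

    def threshold_means(self) -> list[float]:
        return [m for m, _ in self.consensus_thresholds]


def select_components(
    values: Sequence[float],
    K_candidates: Sequence[int] = (1, 2, 3, 4, 5),
    n_iterations: int = 1000,
    subsample_fraction: float = 0.9,
    criterion: Literal["bic", "aic"] = "bic",
    seed: int | None = None,
) -> ResampleSelection:
    """Choose the number of mixture components by a resampling vote.

    Each iteration draws a subsample without replacement (default 90%
    of the data), fits every candidate K and scores the fits by BIC
    (AIC optional); the iteration votes for the best-scoring K. The
    chosen K is the majority vote, with ties broken toward the smaller
    K (parsimony). Consensus thresholds are the per-boundary means (and
    sds) of the thresholds from the iterations whose optimum equals the
    chosen K.
    """
    x = np.asarray(values, float).ravel()
    K_candidates = sorted(set(int(k) for k in K_candidates))
    if not K_candidates:
        raise ValidationError("K_candidates must be non-empty")
    m = int(np.floor(len(x) * subsample_fraction))
    if m < max(K_candidates):
        raise InsufficientDataError(
            f"subsample size {m} < max candidate K {max(K_candidates)}"
        )
    rng = np.random.default_rng(seed)
    votes: Counter[int] = Counter()
    thresholds_by_K: dict[int, list[list[float]]] = {k: [] for k in K_candidates}
    for _ in range(n_iterations):
        sub = rng.choice(x, size=m, replace=False)
        best_k, best_score, best_model = None, np.inf, None
        for k in K_candidates:
            try:
                model = fit_gmm_1d(sub, k, seed=int(rng.integers(2**31)))
            except (InsufficientDataError, DegenerateDataError):
                continue
            score = model.bic(m) if criterion == "bic" else model.aic()
            # strict < keeps ties at the smaller K (candidates ascend)
            if score < best_score:
                best_k, best_score, best_model = k, score, model
        if best_k is None:
            continue
        votes[best_k] += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            thresholds_by_K[best_k].append(thresholds_from_mixture(best_model))
    if not votes:
        raise DegenerateDataError("no iteration produced a valid fit")
    chosen_K = majority_vote(votes)
    qualifying = thresholds_by_K[chosen_K]
    consensus: list[tuple[float, float]] = []
    if chosen_K > 1 and qualifying:
        arr = np.asarray(qualifying, float)  # iterations x (K-1)
        consensus = [
            (float(arr[:, j].mean()), float(arr[:, j].std(ddof=1)) if len(arr) > 1 else 0.0)
            for j in range(chosen_K - 1)
        ]
    return ResampleSelection(
        votes=dict(sorted(votes.items())),
        chosen_K=chosen_K,
        qualifying_iterations=len(qualifying),
        consensus_thresholds=consensus,
    )


STRATA_LABELS = {1: ["low", "high"], 2: ["low", "intermediate", "high"]}


@dataclass
class StrataAssignment:
    """Per-sample low/intermediate/high category calls."""

    categories: pd.Series  # sample_id -> label
    thresholds: list[float]
    labels: list[str]


def classify(
    values: pd.Series | Sequence[float],
    thresholds: Sequence[float],
    labels: Sequence[str] | None = None,
) -> StrataAssignment:
    """Assign each value to a stratum by ordered thresholds.

    With thresholds (t1, t2): value < t1 -> low, t1 <= value < t2 ->
    intermediate, value >= t2 -> high; a value exactly on a boundary
    goes to the upper category. One threshold yields low/high; an empty
    threshold list puts everything in a single category.
    """
    thresholds = [float(t) for t in thresholds]
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValidationError(f"thresholds must be strictly increasing: {thresholds}")
    if labels is None:
        labels = STRATA_LABELS.get(len(thresholds))
        if labels is None:
            labels = (
                ["all"]
                if not thresholds
                else [f"stratum_{i}" for i in range(len(thresholds) + 1)]
            )
    labels = list(labels)
    if len(labels) != len(thresholds) + 1:
        raise ValidationError("need exactly len(thresholds)+1 labels")
    s = pd.Series(values, dtype=float)
    idx = np.searchsorted(thresholds, s.to_numpy(), side="right")
    cats = pd.Series(pd.Categorical.from_codes(idx, categories=labels), index=s.index)
    return StrataAssignment(categories=cats, thresholds=thresholds, labels=labels)


TMA_REQUIRED = ["core_id", "artifact_area_fraction", "tumor_area_fraction"]


def validate_tma_table(table: pd.DataFrame) -> None:
    missing = [c for c in TMA_REQUIRED if c not in table.columns]
    if missing:
        raise ValidationError(f"TMA table missing columns: {missing}")
    for c in ("artifact_area_fraction", "tumor_area_fraction"):
        v = table[c].to_numpy(float)
        if ((v < 0) | (v > 1)).any():
            raise ValidationError(f"{c} outside [0,1]")
    if "pt_stage" in table.columns and len(table):
        st = table["pt_stage"].to_numpy()
        if not np.isin(st, [1, 2, 3, 4]).all():
            raise ValidationError("pt_stage must be in {1,2,3,4}")


@dataclass
class QcReport:
    """Thresholds and survivor counts from the 3-step core filter."""

    mode: str
    artifact_threshold: float | None
    tumor_threshold: float | None
    n_input: int
    n_after_artifact: int
    n_after_tumor: int
    n_after_ratio: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def qc_filter_cores(
    table: pd.DataFrame,
    mode: Literal["fit", "fixed"] = "fit",
    fixed_thresholds: tuple[float, float] | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, QcReport]:
    """Three-step tissue-microarray core QC filter.

    Step 1 fits a 2-component mixture to the artifact area fractions
    and keeps cores below the boundary of the lowest component (low
    artifact). Step 2 refits on the survivors' tumor area fractions and
    keeps cores above the boundary (high tumor content). Step 3 keeps
    cores whose tumor fraction exceeds their artifact fraction. In
    ``fixed`` mode the supplied (artifact, tumor) thresholds are
    applied without refitting.
    """
    validate_tma_table(table)
    if mode == "fixed":
        if fixed_thresholds is None:
            raise ValidationError("fixed mode requires fixed_thresholds=(artifact, tumor)")
        t_art, t_tum = (float(t) for t in fixed_thresholds)
    n0 = len(table)
    if n0 == 0:
        rep = QcReport(mode, None, None, 0, 0, 0, 0)
        return table.copy(), rep
    if mode == "fit":
        try:
            m_art = fit_gmm_1d(
                table["artifact_area_fraction"].to_numpy(float), K=2, seed=seed
            )
            t_art = thresholds_from_mixture(m_art)[0]
        except (DegenerateDataError, InsufficientDataError) as e:
            raise DegenerateDataError(
                f"artifact-fraction mixture degenerate ({e}); use mode='fixed'"
            ) from e
    step1 = table[table["artifact_area_fraction"] < t_art]
    if mode == "fit":
        try:
            m_tum = fit_gmm_1d(
                step1["tumor_area_fraction"].to_numpy(float), K=2, seed=seed
            )
            t_tum = thresholds_from_mixture(m_tum)[0]
        except (DegenerateDataError, InsufficientDataError) as e:
            raise DegenerateDataError(
                f"tumor-fraction mixture degenerate ({e}); use mode='fixed'"
            ) from e
    step2 = step1[step1["tumor_area_fraction"] > t_tum]
    step3 = step2[step2["tumor_area_fraction"] > step2["artifact_area_fraction"]]
    rep = QcReport(
        mode=mode,
        artifact_threshold=float(t_art),
        tumor_threshold=float(t_tum),
        n_input=n0,
        n_after_artifact=len(step1),
        n_after_tumor=len(step2),
        n_after_ratio=len(step3),
    )
    return step3.copy(), rep
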