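"""Seeded synthetic datasets with the structure the analysis assumes.

Three generators emulate the study's analytic inputs at desk scale:

* ``simulate_screen`` — a pooled shRNA dropout screen: per-hairpin log2
  abundance declines linearly over timepoints 0/1/2 (the two sampling
  points after roughly 3 and 6 population doublings, plus baseline),
  ~5 hairpins per gene, 3 replicates, matched primary/metastatic cell
  lines, and a configurable subset of metastatic lines that are
  dependent on the designated differential genes (the bimodal
  dependency split).
* ``simulate_tma`` — a tissue-microarray core table: artifact/tumor
  area fractions and per-marker positive-cell fractions drawn from 2-3
  component Gaussian mixtures on [0,1], with pT stage drawn from
  class-dependent log-odds so the upper expression class can be
  enriched in late stages.
* ``simulate_expression`` — paired log2 expression matrices with
  designated genes shifted consistently (or inconsistently, for
  testing the concordance rule) across patient pairs.

Every generator is a pure function of its config and seed: one global
seed is expanded into independent per-stream sub-seeds so that adding
a marker or gene stream does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .screen import ScreenDataset


def _check(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {msg}")


@dataclass
class ScreenSimConfig:
    """Parameters of the synthetic dropout screen.

    Slopes are log2-abundance change per timepoint unit; negative means
    dropout (essential). ``differential_gene_ids`` are essential only
    in the dependent metastatic lines; genes drawn as globally
    essential drop out everywhere.
    """

    n_genes: int = 200
    hairpins_per_gene_mean: float = 5.0
    n_primary_lines: int = 3
    n_metastatic_lines: int = 3
    frac_metastatic_dependent: float = 0.5
    essential_gene_frac: float = 0.1
    differential_gene_ids: tuple[str, ...] = ()
    slope_essential: float = -1.0
    slope_neutral: float = 0.0
    timepoints: tuple[int, ...] = (0, 1, 2)
    n_replicates: int = 3
    baseline_mean: float = 9.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.hairpins_per_gene_mean >= 1, "hairpins_per_gene_mean", "must be >= 1")
        _check(self.n_primary_lines >= 1, "n_primary_lines", "must be >= 1")
        _check(self.n_metastatic_lines >= 1, "n_metastatic_lines", "must be >= 1")
        _check(
            0 <= self.frac_metastatic_dependent <= 1,
            "frac_metastatic_dependent",
            "must be in [0, 1]",
        )
        _check(0 <= self.essential_gene_frac <= 1, "essential_gene_frac", "must be in [0, 1]")
        tp = list(self.timepoints)
        _check(len(tp) >= 2 and all(b > a for a, b in zip(tp, tp[1:])),
               "timepoints", "must be strictly increasing with >=2 values")
        _check(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _check(self.baseline_sd >= 0, "baseline_sd", "must be >= 0")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")


@dataclass
class SimulatedScreen:
    """A synthetic screen plus its generating truth."""

    dataset: ScreenDataset
    true_slopes: pd.DataFrame  # genes x lines
    essential_genes: list[str]
    differential_genes: list[str]
    dependent_lines: list[str]
    config: ScreenSimConfig


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(n)]


def simulate_screen(config: ScreenSimConfig) -> SimulatedScreen:
    """Generate a long-format pooled-screen abundance table.

    Each hairpin's log2 abundance is ``baseline_h + slope(gene, line) *
    t + N(0, noise_sd)`` with the baseline drawn once per hairpin.
    Hairpin counts per gene are Poisson(mean) truncated at >= 1.
    Deterministic given the config seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_base, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    genes = _gene_ids(config.n_genes)
    unknown = set(config.differential_gene_ids) - set(genes)
    _check(not unknown, "differential_gene_ids", f"not among generated genes: {sorted(unknown)}")

    n_ess = int(round(config.essential_gene_frac * config.n_genes))
    candidates = [g for g in genes if g not in config.differential_gene_ids]
    essential = sorted(
        str(g)
        for g in rng_struct.choice(candidates, size=min(n_ess, len(candidates)), replace=False)
    )

    primary = [f"pri{i}" for i in range(config.n_primary_lines)]
    metastatic = [f"met{i}" for i in range(config.n_metastatic_lines)]
    n_dep = int(round(config.frac_metastatic_dependent * config.n_metastatic_lines))
    dependent = sorted(str(l) for l in rng_struct.choice(metastatic, size=n_dep, replace=False))

    # hairpins per gene: Poisson truncated at >=1 by rejection
    counts = rng_struct.poisson(config.hairpins_per_gene_mean, size=config.n_genes)
    while (counts == 0).any():
        redo = counts == 0
        counts[redo] = rng_struct.poisson(config.hairpins_per_gene_mean, size=int(redo.sum()))

    lines = primary + metastatic
    group_of = {l: ("primary" if l in primary else "metastatic") for l in lines}
    ess_set, diff_set, dep_set = set(essential), set(config.differential_gene_ids), set(dependent)

    def true_slope(gene: str, line: str) -> float:
        if gene in ess_set:
            return config.slope_essential
        if gene in diff_set and line in dep_set:
            return config.slope_essential
        return config.slope_neutral

    tps = np.asarray(config.timepoints, float)
    nrep = config.n_replicates
    n_cells = len(lines) * len(tps) * nrep

    frames = []
    for gi, gene in enumerate(genes):
        for h in range(int(counts[gi])):
            hp = f"{gene}_sh{h}"
            base = rng_base.normal(config.baseline_mean, config.baseline_sd)
            noise = (
                rng_noise.normal(0.0, config.noise_sd, size=n_cells)
                if config.noise_sd > 0
                else np.zeros(n_cells)
            )
            k = 0
            for line in lines:
                s = true_slope(gene, line)
                for t in tps:
                    for r in range(nrep):
                        frames.append(
                            (hp, gene, line, group_of[line], int(t), r,
                             base + s * t + noise[k])
                        )
                        k += 1
    table = pd.DataFrame(
        frames,
        columns=["hairpin_id", "gene_id", "line_id", "group", "timepoint",
                 "replicate", "log2_abundance"],
    )
    truth = pd.DataFrame(
        [[true_slope(g, l) for l in lines] for g in genes],
        index=genes,
        columns=lines,
    )
    return SimulatedScreen(
        dataset=ScreenDataset(table),
        true_slopes=truth,
        essential_genes=list(essential),
        differential_genes=list(config.differential_gene_ids),
        dependent_lines=list(dependent),
        config=config,
    )


@dataclass
class MixtureSpec:
    """A K-component Gaussian mixture on the fraction scale [0, 1]."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def validate(self, name: str = "mixture") -> None:
        k = len(self.weights)
        _check(k >= 1, name, "needs >=1 component")
        _check(len(self.means) == k and len(self.sds) == k, name,
               "weights/means/sds lengths differ")
        _check(abs(sum(self.weights) - 1.0) < 1e-9, name, "weights must sum to 1")
        _check(all(w >= 0 for w in self.weights), name, "weights must be >= 0")
        _check(all(0 <= m <= 1 for m in self.means), name, "means must be in [0, 1]")
        _check(all(s >= 0 for s in self.sds), name, "sds must be >= 0")

    @property
    def K(self) -> int:
        return len(self.weights)


def _draw_mixture(
    rng: np.random.Generator, spec: MixtureSpec, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n values from the mixture, truncated to [0,1] by resampling.

    Resampling (rather than clipping) avoids probability atoms at the
    boundaries, so downstream EM fits still see mixture-shaped data.
    """
    classes = rng.choice(spec.K, size=n, p=np.asarray(spec.weights))
    means = np.asarray(spec.means)[classes]
    sds = np.asarray(spec.sds)[classes]
    out = rng.normal(means, sds)
    bad = (out < 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(means[bad], sds[bad])
        bad = (out < 0) | (out > 1)
    return out, classes


@dataclass
class TmaSimConfig:
    """Parameters of the synthetic tissue-microarray core table.

    ``late_stage_logodds_by_class`` maps latent classes of the
    ``stage_marker`` to the log-odds of a late pT stage (3-4), so the
    upper expression class can be enriched in late stages.
    """

    n_cores: int = 200
    markers: Mapping[str, MixtureSpec] = field(
        default_factory=lambda: {
            "marker": MixtureSpec((0.4, 0.35, 0.25), (0.1, 0.4, 0.75), (0.05, 0.07, 0.08))
        }
    )
    artifact_mixture: MixtureSpec = field(
        default_factory=lambda: MixtureSpec((0.65, 0.35), (0.03, 0.25), (0.015, 0.08))
    )
    tumor_mixture: MixtureSpec = field(
        default_factory=lambda: MixtureSpec((0.2, 0.8), (0.15, 0.6), (0.05, 0.12))
    )
    stage_marker: str = "marker"
    late_stage_logodds_by_class: tuple[float, ...] = (-1.1, 0.0, 1.1)
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_cores >= 1, "n_cores", "must be >= 1")
        _check(len(self.markers) >= 1, "markers", "need >=1 marker")
        for name, spec in self.markers.items():
            spec.validate(f"markers[{name}]")
            _check(spec.K in (2, 3), f"markers[{name}]", "K must be 2 or 3")
        self.artifact_mixture.validate("artifact_mixture")
        self.tumor_mixture.validate("tumor_mixture")
        _check(self.artifact_mixture.K == 2, "artifact_mixture", "must have 2 components")
        _check(self.tumor_mixture.K == 2, "tumor_mixture", "must have 2 components")
        _check(self.stage_marker in self.markers, "stage_marker", "not among markers")
        _check(
            len(self.late_stage_logodds_by_class) == self.markers[self.stage_marker].K,
            "late_stage_logodds_by_class",
            "length must equal the stage marker's component count",
        )


def simulate_tma(config: TmaSimConfig) -> pd.DataFrame:
    """Generate a per-core TMA table.

    Columns: core_id, artifact_area_fraction, tumor_area_fraction, one
    fraction column per marker, the latent class per marker
    (``class_<marker>``), and pt_stage in {1,2,3,4}. Deterministic
    given the config seed.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(3 + len(config.markers))
    rng_art = np.random.default_rng(streams[0])
    rng_tum = np.random.default_rng(streams[1])
    rng_stage = np.random.default_rng(streams[2])

    n = config.n_cores
    out = pd.DataFrame({"core_id": [f"core{i:04d}" for i in range(n)]})
    out["artifact_area_fraction"], _ = _draw_mixture(rng_art, config.artifact_mixture, n)
    out["tumor_area_fraction"], _ = _draw_mixture(rng_tum, config.tumor_mixture, n)

    marker_class: dict[str, np.ndarray] = {}
    for (name, spec), stream in zip(sorted(config.markers.items()), streams[3:]):
        rng_m = np.random.default_rng(stream)
        vals, classes = _draw_mixture(rng_m, spec, n)
        out[name] = vals
        out[f"class_{name}"] = classes
        marker_class[name] = classes

    logodds = np.asarray(config.late_stage_logodds_by_class)[
        marker_class[config.stage_marker]
    ]
    p_late = 1.0 / (1.0 + np.exp(-logodds))
    late = rng_stage.random(n) < p_late
    # within early/late, the two constituent stages are equally likely
    sub = rng_stage.integers(0, 2, size=n)
    out["pt_stage"] = np.where(late, 3 + sub, 1 + sub)
    return out


def simulate_expression(
    n_genes: int,
    n_pairs: int,
    de_gene_spec: Mapping[str, int | Sequence[int]] | None = None,
    fold: float = 1.5,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate paired log2 expression matrices.

    ``de_gene_spec`` maps gene ids to +1/-1 (metastatic up/down by
    log2(fold) in every pair) or to a per-pair sequence of directions
    to construct discordant genes. Returns (matrix, design): the matrix
    is genes x samples (log2 scale, ``n_replicates`` samples per pair
    and site), the design maps each sample to its pair and site.
    """
    if fold <= 1:
        raise ValidationError(f"fold: must be > 1, got {fold}")
    if n_pairs < 1:
        raise ValidationError("n_pairs: must be >= 1")
    de_gene_spec = dict(de_gene_spec or {})
    genes = _gene_ids(n_genes)
    unknown = set(de_gene_spec) - set(genes)
    if unknown:
        raise ValidationError(f"de_gene_spec: unknown genes {sorted(unknown)}")

    shift = np.zeros((n_genes, n_pairs))
    for g, direction in de_gene_spec.items():
        gi = genes.index(g)
        dirs = np.broadcast_to(np.asarray(direction, float), (n_pairs,))
        shift[gi] = dirs * np.log2(fold)

    ss = np.random.SeedSequence(seed)
    rng_base, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    base = rng_base.normal(7.0, 1.0, size=n_genes)

    cols, data, design_rows = [], [], []
    for p in range(n_pairs):
        for site, delta in (("primary", 0.0), ("metastatic", 1.0)):
            for r in range(n_replicates):
                name = f"pair{p}_{site}_r{r}"
                cols.append(name)
                noise = (
                    rng_noise.normal(0, noise_sd, size=n_genes)
                    if noise_sd > 0
                    else np.zeros(n_genes)
                )
                data.append(base + delta * shift[:, p] + noise)
                design_rows.append((name, f"pair{p}", site))
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    design = pd.DataFrame(design_rows, columns=["sample", "pair", "site"]).set_index("sample")
    return matrix, design
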