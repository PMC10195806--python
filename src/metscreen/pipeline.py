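"""End-to-end orchestration of the two analyses.

``run_screen_analysis`` chains hairpin trajectory fitting, per-gene
differential essentiality and the per-gene bimodal dependency split;
``run_tma_analysis`` chains core QC, per-marker component selection and
thresholding, stratum assignment and stage-association testing. Both
read plain CSV/TSV, write CSV/JSON outputs and return a ``RunReport``
echoing every parameter, count, threshold and seed, so each reported
number is traceable to a stage output file.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .errors import ValidationError
from .mixture import (
    classify,
    qc_filter_cores,
    select_components,
    validate_tma_table,
)
from .screen import (
    ScreenDataset,
    bimodal_dependency_analysis,
    differential_essentiality,
    line_scores,
)
from .stats import bh_adjust, chisq_test, crosstab_proportions

logger = logging.getLogger("metscreen")


def codon_of_cds_position(cds_position: int) -> tuple[int, int]:
    """Map a 1-based coding-sequence nucleotide index to its codon.

    Returns (codon_index, position_in_codon), both 1-based; e.g. the
    c.1939C>T substitution falls on position 1 of codon 647.
    """
    if cds_position < 1:
        raise ValidationError(f"cds_position must be >= 1, got {cds_position}")
    pos0 = cds_position - 1
    return pos0 // 3 + 1, pos0 % 3 + 1


@dataclass
class RunReport:
    """Parameter echo plus per-stage counts, thresholds and results."""

    analysis: str
    parameters: dict[str, Any] = field(default_factory=dict)
    stages: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"analysis": self.analysis, "seed": self.seed,
             "parameters": self.parameters, "stages": self.stages},
            indent=2, sort_keys=True, default=_jsonable,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def _jsonable(obj: Any) -> Any:
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    if hasattr(obj, "item"):
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    return str(obj)


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a YAML mapping")
    return cfg


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            logger.info("stage %s: done in %.2fs", stage, time.perf_counter() - self.t0)
            return False

    return _Timer()


def run_screen_analysis(
    dataset: ScreenDataset | str | Path,
    out_dir: str | Path,
    method: str = "auto",
    bimodal_genes: list[str] | None = None,
    bimodal_q: float = 0.05,
    seed: int = 0,
) -> RunReport:
    """Screen chain: trajectory fits -> differential test -> bimodality.

    ``bimodal_genes`` explicitly selects genes for the per-gene
    dependency split; by default every gene with q < ``bimodal_q``
    and >= 4 scored metastatic lines is analysed.
    """
    if not isinstance(dataset, ScreenDataset):
        dataset = ScreenDataset.from_tsv(dataset)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        analysis="screen",
        seed=seed,
        parameters={"method": method, "bimodal_genes": bimodal_genes, "bimodal_q": bimodal_q},
    )

    if len(dataset.table) == 0:
        pd.DataFrame(columns=["gene_id", "delta", "p_value", "q_value"]).to_csv(
            out / "essentiality_records.csv", index=False
        )
        pd.DataFrame().to_csv(out / "line_scores.csv")
        report.stages["differential"] = {"n_genes": 0, "n_significant_q05": 0, "top_gene": None}
        report.stages["line_scores"] = {"n_genes": 0, "n_lines": 0, "n_missing": 0}
        report.stages["bimodality"] = {"analysed_genes": [], "skipped": "empty dataset", "results": {}}
        report.to_json(out / "screen_report.json")
        return report

    with _timed("differential"):
        records = differential_essentiality(dataset, method=method)
    records.to_csv(out / "essentiality_records.csv", index=False)
    report.stages["differential"] = {
        "n_genes": len(records),
        "n_significant_q05": int((records["q_value"] < 0.05).sum()),
        "top_gene": records["gene_id"].iloc[0] if len(records) else None,
    }

    with _timed("line_scores"):
        matrix = line_scores(dataset)
    matrix.to_csv(out / "line_scores.csv")
    report.stages["line_scores"] = {
        "n_genes": matrix.scores.shape[0],
        "n_lines": matrix.scores.shape[1],
        "n_missing": int(matrix.missing_mask().to_numpy().sum()),
    }

    groups = dataset.grouping()
    n_met_lines = sum(1 for g in groups.values() if g == "metastatic")
    if bimodal_genes is None:
        bimodal_genes = records.loc[records["q_value"] < bimodal_q, "gene_id"].tolist()
    bimodal_out: dict[str, Any] = {}
    if n_met_lines >= 4:
        with _timed("bimodality"):
            for gene in bimodal_genes:
                scores = matrix.scores.loc[gene].dropna()
                split = bimodal_dependency_analysis(scores, groups)
                bimodal_out[gene] = {
                    "bimodal": split.bimodal,
                    "low_lines": split.low_lines,
                    "high_lines": split.high_lines,
                    "welch_low_vs_high": split.welch_low_vs_high,
                    "welch_low_vs_primary": split.welch_low_vs_primary,
                }
    report.stages["bimodality"] = {
        "analysed_genes": list(bimodal_out),
        "skipped": None if n_met_lines >= 4 else "fewer than 4 metastatic lines",
        "results": bimodal_out,
    }
    report.to_json(out / "screen_report.json")
    return report


def run_tma_analysis(
    table: pd.DataFrame | str | Path,
    out_dir: str | Path,
    markers: list[str] | None = None,
    qc_mode: str = "fit",
    fixed_thresholds: tuple[float, float] | None = None,
    n_iterations: int = 1000,
    subsample_fraction: float = 0.9,
    K_candidates: tuple[int, ...] = (1, 2, 3, 4, 5),
    collapse: Mapping[str, Mapping[str, str]] | None = None,
    simulate_p: bool = True,
    n_replicates: int = 2000,
    crosstab_pairs: list[tuple[str, str]] | None = None,
    seed: int = 0,
) -> RunReport:
    """TMA chain: QC -> per-marker thresholds -> strata -> associations.

    ``collapse`` optionally maps, per marker, stratum labels onto
    coarser ones (e.g. intermediate+high vs low) before the stage
    association test; BH correction runs across the declared family of
    per-marker comparisons.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table)
    validate_tma_table(table)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        analysis="tma",
        seed=seed,
        parameters={
            "qc_mode": qc_mode, "fixed_thresholds": fixed_thresholds,
            "n_iterations": n_iterations, "subsample_fraction": subsample_fraction,
            "K_candidates": list(K_candidates), "simulate_p": simulate_p,
            "n_replicates": n_replicates, "collapse": collapse,
        },
    )

    with _timed("qc"):
        filtered, qc = qc_filter_cores(
            table, mode=qc_mode, fixed_thresholds=fixed_thresholds, seed=seed
        )
    filtered.to_csv(out / "cores_filtered.csv", index=False)
    report.stages["qc"] = qc.to_dict()

    if markers is None:
        reserved = {"core_id", "artifact_area_fraction", "tumor_area_fraction", "pt_stage"}
        markers = [
            c for c in table.columns
            if c not in reserved and not c.startswith("class_")
            and pd.api.types.is_numeric_dtype(table[c])
        ]
    if len(filtered) == 0:
        report.stages["strata"] = {"skipped": "no cores passed QC"}
        report.stages["association"] = {"skipped": "no cores passed QC"}
        report.to_json(out / "tma_report.json")
        return report

    strata_table = filtered[["core_id"]].copy()
    strata: dict[str, Any] = {}
    marker_info: dict[str, Any] = {}
    with _timed("strata"):
        for i, marker in enumerate(markers):
            vals = filtered[marker].to_numpy(float)
            sel = select_components(
                vals, K_candidates, n_iterations=n_iterations,
                subsample_fraction=subsample_fraction, seed=seed + i,
            )
            thresholds = sel.threshold_means()
            assign = classify(pd.Series(vals, index=filtered["core_id"]), thresholds)
            strata[marker] = assign
            strata_table[marker] = assign.categories.to_numpy()
            marker_info[marker] = {
                "votes": sel.votes, "chosen_K": sel.chosen_K,
                "qualifying_iterations": sel.qualifying_iterations,
                "thresholds": thresholds,
            }
    strata_table.to_csv(out / "strata.csv", index=False)
    report.stages["strata"] = marker_info

    assoc: dict[str, Any] = {}
    if "pt_stage" in filtered.columns:
        stage = pd.Series(
            pd.Categorical(
                pd.Series(filtered["pt_stage"].to_numpy()).map(
                    lambda s: "early" if s in (1, 2) else "late"
                ),
                categories=["early", "late"],
            ),
            index=filtered["core_id"],
        )
        pvals, names = [], []
        with _timed("association"):
            for marker in markers:
                cats = strata[marker].categories
                if collapse and marker in collapse:
                    cats = cats.map(collapse[marker]).astype("category")
                ct = pd.crosstab(stage, cats)
                ct = ct.loc[ct.sum(axis=1) > 0, ct.sum(axis=0) > 0]
                if ct.shape[0] < 2 or ct.shape[1] < 2:
                    assoc[marker] = {"skipped": "collapsed table < 2x2"}
                    continue
                res = chisq_test(
                    ct, simulate=simulate_p, n_replicates=n_replicates, seed=seed
                )
                assoc[marker] = {"table": ct.to_dict(), "test": res.to_dict()}
                pvals.append(res.p_value)
                names.append(marker)
        if pvals:
            q = bh_adjust(pvals)
            for name, qv in zip(names, q):
                assoc[name]["q_value"] = float(qv)
    report.stages["association"] = assoc

    crosstabs: dict[str, Any] = {}
    for a, b in crosstab_pairs or []:
        res = crosstab_proportions(strata[a], strata[b])
        crosstabs[f"{a}_x_{b}"] = {
            "counts": res.counts.astype(int).to_dict(),
            "proportions": res.proportions.to_dict(),
        }
    if crosstabs:
        report.stages["crosstabs"] = crosstabs
    report.to_json(out / "tma_report.json")
    return report


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
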