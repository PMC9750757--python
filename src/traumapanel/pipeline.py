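"""End-to-end orchestration: QC -> panel preprocessing -> differential
analyses -> case-control matching -> matched re-analysis -> outcome
prediction (real + permuted control), with a JSON run report recording the
counts at every stage, every derived seed, and any warnings.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import panel as panel_mod
from .containers import patients_from_frame, patients_to_frame
from .differential import cohort_summary, volcano_table, zscore_matrix
from .matching import MatchSpec, classify_outcome, match_case_control
from .prediction import bootstrap_ensemble, model_significance, plsda_scores
from .synthetic import GeneratorConfig, write_fixture

__all__ = ["PipelineConfig", "run_pipeline", "make_fixture", "load_config"]

logger = logging.getLogger("traumapanel")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    matrix_path: str
    metadata_path: str
    manifest_path: str
    qc_path: str | None = None
    output_dir: str = "results"
    # analysis block
    contrasts: tuple = (("R", "NR"),)
    volcano_timepoints: tuple = ("24h", "72h")
    max_missing_fraction: float = 0.20
    fold_threshold: float = 1.5
    alpha: float = 0.05
    # matching block
    matching: MatchSpec = field(default_factory=lambda: MatchSpec(allow_many_to_one=True))
    # prediction block
    prediction_timepoint: str = "72h"
    n_iterations: int = 1000
    draw_size: int = 112
    use_covariates: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.max_missing_fraction <= 0 or self.fold_threshold <= 0 or self.alpha <= 0:
            raise PipelineError("thresholds must be positive")
        for name in ("matrix_path", "metadata_path", "manifest_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise PipelineError(f"{name}: file not found: {p}")
        if self.qc_path is not None and not Path(self.qc_path).exists():
            raise PipelineError(f"qc_path: file not found: {self.qc_path}")


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "matching" in raw:
        raw["matching"] = MatchSpec(**raw["matching"])
    return PipelineConfig(**raw)


def _grouping_fn(meta: pd.DataFrame):
    def fn(sample_id: str):
        row = meta.loc[sample_id]
        return row["group"], row["timepoint"]

    return fn


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow and return the run report (also written to
    ``<output_dir>/run_report.json``)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "warnings": []}
    caught: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        _run_stages(config, outdir, report)
        caught = [str(w.message) for w in wlist]
    report["warnings"] = caught
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _run_stages(config: PipelineConfig, outdir: Path, report: dict) -> None:
    # --- QC ---------------------------------------------------------------
    if config.qc_path:
        qc = panel_mod.read_qc(config.qc_path)
        pass_ids, fail_ids, frac = panel_mod.qc_filter(qc)
        report["stages"]["qc"] = {
            "n_records": len(qc), "n_pass": len(pass_ids),
            "n_fail": len(fail_ids), "pass_fraction": frac,
        }

    # --- Read + preprocess ------------------------------------------------
    matrix, manifest, meta = panel_mod.read_expression(
        config.matrix_path, config.metadata_path, config.manifest_path
    )
    log2m, prep = panel_mod.preprocess_panel(
        matrix, manifest, max_missing_fraction=config.max_missing_fraction
    )
    n_mediators = int(
        manifest.loc[
            manifest.index.intersection(log2m.values.index), "role"
        ].eq("mediator").sum()
    )
    prep["n_mediators"] = n_mediators
    report["stages"]["preprocess"] = {
        k: v for k, v in prep.items() if k != "removed_analytes"
    }
    report["stages"]["preprocess"]["removed_analytes"] = prep["removed_analytes"]

    patients_df = meta.drop_duplicates("patient_id").set_index("patient_id")
    grouping = _grouping_fn(meta)

    # --- Differential analyses --------------------------------------------
    heat = zscore_matrix(log2m, grouping)
    heat.z.rename_axis("analyte_id").to_csv(outdir / "heatmap_z.tsv", sep="\t")
    report["stages"]["heatmap"] = {
        "n_rows": int(heat.z.shape[0]),
        "n_cells": int(heat.z.shape[1]),
        "n_degenerate_rows": int(heat.degenerate.sum()),
    }

    volcanoes = {}
    for (ga, gb) in config.contrasts:
        for tp in config.volcano_timepoints:
            v = volcano_table(log2m, grouping, tp, group_a=ga, group_b=gb)
            key = f"{ga}_vs_{gb}_{tp}"
            v.to_csv(outdir / f"volcano_{key}.csv")
            volcanoes[key] = int(v["significant"].sum())
    report["stages"]["volcano"] = {"n_significant": volcanoes}

    summary = cohort_summary(
        patients_df[patients_df["group"] != "CONTROL"],
        patients_df.loc[patients_df["group"] != "CONTROL", "group"],
    )
    summary.to_csv(outdir / "cohort_summary.csv")

    # --- Matching + matched re-analysis ------------------------------------
    plist = patients_from_frame(
        patients_df.drop(columns=[c for c in ("timepoint", "group") if c in patients_df])
    )
    by_group: dict = {}
    for p in plist:
        by_group.setdefault(classify_outcome(p), []).append(p)
    match = match_case_control(
        by_group.get("NR", []), by_group.get("R", []), config.matching,
        seed=config.seed,
    )
    matched_ids = {p.patient_id for p in match.matched_cases} | {
        p.patient_id for p in match.matched_controls
    }
    report["stages"]["matching"] = {
        "n_matched_cases": len(match.matched_cases),
        "n_matched_controls": len(match.matched_controls),
        "balance": match.balance,
    }
    pairs_df = pd.DataFrame(match.pairs, columns=["case_id", "control_id"])
    pairs_df.to_csv(outdir / "matched_pairs.csv", index=False)

    matched_samples = meta.index[meta["patient_id"].isin(matched_ids)]
    if len(matched_samples):
        log2_matched, _ = panel_mod.preprocess_panel(
            matrix, manifest, max_missing_fraction=config.max_missing_fraction,
            sample_ids=list(matched_samples),
        )
        heat_m = zscore_matrix(log2_matched, grouping)
        heat_m.z.rename_axis("analyte_id").to_csv(
            outdir / "heatmap_z_matched.tsv", sep="\t"
        )
        report["stages"]["matched_analysis"] = {
            "n_samples": int(log2_matched.n_samples),
            "n_analytes": int(log2_matched.n_analytes),
        }

    # --- Prediction ---------------------------------------------------------
    tp = config.prediction_timepoint
    pred_samples = meta.index[
        meta["group"].isin(["R", "NR"]) & (meta["timepoint"] == tp)
    ]
    mediator_ids = [
        a for a in log2m.values.index
        if manifest.loc[a, "role"] == "mediator"
    ]
    Xdf = log2m.values.loc[mediator_ids, pred_samples].T
    y = (meta.loc[pred_samples, "group"] == "NR").astype(int).to_numpy()
    if config.use_covariates:
        from .prediction import augment_covariates

        cov = meta.loc[pred_samples, ["iss", "age", "sex"]]
        Xdf = augment_covariates(Xdf, cov)
    real = bootstrap_ensemble(
        Xdf.to_numpy(), y, B=config.n_iterations,
        draw_size=min(config.draw_size, len(y)), seed=config.seed,
        feature_names=list(Xdf.columns),
    )
    control = bootstrap_ensemble(
        Xdf.to_numpy(), y, B=config.n_iterations,
        draw_size=min(config.draw_size, len(y)), seed=config.seed,
        feature_names=list(Xdf.columns), permute_labels=True,
    )
    real.comparison_p = model_significance(real, control)
    report["stages"]["prediction"] = {
        "timepoint": tp,
        "n_samples": int(len(y)),
        "n_features": int(Xdf.shape[1]),
        "real": real.to_dict(),
        "control": control.to_dict(),
    }
    (outdir / "model_summary.json").write_text(
        json.dumps({"real": real.to_dict(), "control": control.to_dict()}, indent=1)
    )
    scores, explained = plsda_scores(Xdf.to_numpy(), y)
    pd.DataFrame(
        scores, index=Xdf.index, columns=[f"LV{k+1}" for k in range(scores.shape[1])]
    ).assign(outcome=y).to_csv(outdir / "plsda_scores.csv")
    report["stages"]["plsda"] = {"explained_x_variance": explained.tolist()}


def make_fixture(outdir, seed: int = 0, scale: str = "paper") -> dict:
    """Write a complete synthetic input set.

    ``tiny``: 12 patients x 20 analytes, for fast unit-level runs.
    ``paper``: the full calibration profile (150 trauma patients + 29
    controls, 184 analytes).
    """
    if scale == "tiny":
        config = GeneratorConfig(
            group_sizes={"ENS": 3, "R": 3, "NR": 4, "CONTROL": 2},
            n_analytes_per_family={
                "IL": 5, "CCL": 3, "CXCL": 2, "IFN": 2, "TNFSF": 2,
                "IL_R": 3, "IFN_R": 1, "TNFRSF": 2,
            },
            delayed_subset_fraction=0.2,
            seed=seed,
        )
    elif scale == "paper":
        config = GeneratorConfig(seed=seed)
    else:
        raise ValueError(f"make_fixture: unknown scale {scale!r}")
    return write_fixture(outdir, config)
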