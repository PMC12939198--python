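"""End-to-end orchestration: gate → compartments → spatial → survival.

A run consumes a cell table (one CSV with a ``sample_id`` column, or a
directory of per-sample CSVs) plus a per-patient clinical table, executes
the stages in order, and writes a run directory with per-stage outputs and
a manifest (parameter echo + SHA-256 of every output file). Runs are
deterministic: identical config and inputs reproduce bit-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compartments import TumorRegionBuilder, compartment_areas_mm2
from .config import CompartmentParams, GatingConfig, SpatialParams
from .io import read_cells, read_cohort, sha256_file, write_region
from .phenotyping import PhenotypeGater
from .spatial import gcross, sample_qc, summarize_sample
from .survival import cox_model, km_logrank

logger = logging.getLogger(__name__)

DEFAULT_PHENOTYPES = ("naive_trm", "exhausted_trm", "pd1_cd8", "cd8")


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and offending sample."""


@dataclass
class RunConfig:
    cells_path: str | Path
    cohort_path: str | Path
    out_dir: str | Path
    gating: GatingConfig
    compartment: CompartmentParams = field(default_factory=CompartmentParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    phenotypes: tuple[str, ...] = DEFAULT_PHENOTYPES
    survival_features: tuple[str, ...] = ()
    window: tuple[float, float] | None = None
    cutpoint_rule: str | float = "median"
    adjust_pvalues: bool = False  # optional Benjamini-Hochberg across features
    seed: int = 0


def _load_samples(cells_path: str | Path) -> dict[str, pd.DataFrame]:
    path = Path(cells_path)
    if path.is_dir():
        frames = [read_cells(p) for p in sorted(path.glob("*.csv"))]
        if not frames:
            raise FileNotFoundError(f"no cell CSVs found under {path}")
        cells = pd.concat(frames, ignore_index=True)
    else:
        cells = read_cells(path)
    return {sid: df.reset_index(drop=True) for sid, df in cells.groupby("sample_id", sort=True)}


def _window_for(cells: pd.DataFrame, window) -> tuple[float, float]:
    if window is not None:
        return tuple(window)
    return (
        float(np.ceil(cells["x_um"].max())) or 1.0,
        float(np.ceil(cells["y_um"].max())) or 1.0,
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory. Halts on stage failure."""
    out = Path(config.out_dir)
    (out / "samples").mkdir(parents=True, exist_ok=True)
    samples = _load_samples(config.cells_path)
    cohort = read_cohort(config.cohort_path)
    gater = PhenotypeGater(config.gating)
    summaries, exclusions, feature_rows = [], [], []
    for sid, cells in samples.items():
        stage = "gate"
        try:
            gated = gater.fit_transform(cells)
            stage = "compartments"
            builder = TumorRegionBuilder(
                config.compartment.dilation_radius_um, config.compartment.min_component
            )
            comp = builder.fit_transform(gated)
            write_region(builder.region_, out / "samples" / f"{sid}_region.geojson")
            stage = "spatial"
            if not sample_qc(comp, config.spatial.min_combined):
                exclusions.append({"sample_id": sid, "reason": f"fewer than {config.spatial.min_combined} combined tumor+CD8 cells in tumor tissue"})
                continue
            win = _window_for(cells, config.window)
            areas = compartment_areas_mm2(builder.region_, win)
            areas = {k: v for k, v in areas.items() if v > 0}
            summary = summarize_sample(
                comp,
                areas,
                config.phenotypes,
                r_max_um=config.spatial.r_max_um,
                n_r=config.spatial.n_r,
                band_width_um=config.spatial.band_width_um,
                max_band_dist_um=config.spatial.max_band_dist_um,
                interaction_radius_um=config.spatial.interaction_radius_um,
                border_correction=config.spatial.border_correction,
                window=(0.0, 0.0, win[0], win[1]),
            )
            summaries.append(summary)
            row = {"sample_id": sid}
            for phen in config.phenotypes:
                curve = gcross(
                    comp, phen, r_max_um=config.spatial.r_max_um, n_r=config.spatial.n_r,
                    border_correction=config.spatial.border_correction,
                    window=(0.0, 0.0, win[0], win[1]),
                )
                curve.to_frame().to_csv(out / "samples" / f"{sid}_{phen}_gcross.csv", index=False)
                row[f"{phen}_gcross_score"] = curve.score
                sub = summary[(summary["phenotype"] == phen) & (summary["compartment"] == "intra_tumor")]
                if len(sub):
                    row[f"{phen}_intra_density"] = float(sub["density_per_mm2"].iloc[0])
                row[f"{phen}_mean_nn_dist_um"] = float(summary.loc[summary["phenotype"] == phen, "mean_nn_dist_um"].iloc[0])
            feature_rows.append(row)
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed for sample {sid!r}: {exc}") from exc
    if summaries:
        pd.concat(summaries, ignore_index=True).to_csv(out / "spatial_summary.csv", index=False)
    else:
        pd.DataFrame().to_csv(out / "spatial_summary.csv", index=False)
    pd.DataFrame(exclusions, columns=["sample_id", "reason"]).to_csv(out / "exclusions.csv", index=False)
    features = pd.DataFrame(feature_rows)
    merged = cohort.drop(columns=[c for c in cohort.columns if c.endswith(("_gcross_score", "_intra_density", "_mean_nn_dist_um", "_z"))], errors="ignore")
    merged = merged.merge(features, on="sample_id", how="inner") if len(features) else merged.iloc[0:0]
    merged.to_csv(out / "cohort_features.csv", index=False)
    _survival_stage(merged, config, out)
    _write_manifest(config, out)
    return out


def _survival_stage(merged: pd.DataFrame, config: RunConfig, out: Path) -> None:
    feats = list(config.survival_features) or [f"{p}_gcross_score" for p in config.phenotypes]
    feats = [f for f in feats if f in merged.columns]
    rows = []
    if len(merged) == 0 or not feats:
        logger.warning("survival stage: no samples passed QC; writing empty results")
        pd.DataFrame(columns=["feature", "analysis", "term", "estimate", "p"]).to_csv(
            out / "survival_results.csv", index=False
        )
        return
    for f in feats:
        try:
            km = km_logrank(merged, f, cutpoint_rule=config.cutpoint_rule)
            rows.append({"feature": f, "analysis": "logrank", "term": f"median_split@{km.cutpoint:.6g}",
                         "estimate": km.chi2, "p": km.p})
            for name, curve in km.curves.items():
                curve.to_csv(out / f"km_{f}_{name}.csv", index=False)
        except ValueError as exc:
            rows.append({"feature": f, "analysis": "logrank", "term": "failed", "estimate": float("nan"), "p": float("nan")})
            logger.warning("log-rank failed for %s: %s", f, exc)
        try:
            cox = cox_model(merged, [f], mode="multivariate")
            if cox.converged and cox.terms is not None:
                for _, t in cox.terms.iterrows():
                    rows.append({"feature": f, "analysis": "cox_multivariate", "term": t["term"],
                                 "estimate": t["hr"], "p": t["p"], "hr_ci_low": t["hr_ci_low"],
                                 "hr_ci_high": t["hr_ci_high"], "coef": t["coef"], "se": t["se"]})
            else:
                rows.append({"feature": f, "analysis": "cox_multivariate", "term": "fit_failure",
                             "estimate": float("nan"), "p": float("nan")})
        except ValueError as exc:
            rows.append({"feature": f, "analysis": "cox_multivariate", "term": "failed",
                         "estimate": float("nan"), "p": float("nan")})
            logger.warning("Cox failed for %s: %s", f, exc)
    results = pd.DataFrame(rows)
    if config.adjust_pvalues:
        from .survival import adjust_pvalues

        lr = results["analysis"] == "logrank"
        results.loc[lr, "p_adjusted"] = adjust_pvalues(results.loc[lr, "p"])
    results.to_csv(out / "survival_results.csv", index=False)


def _write_manifest(config: RunConfig, out: Path) -> None:
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "parameters": {
            "gating_thresholds": dict(config.gating.thresholds),
            "hierarchy": [r.name for r in config.gating.hierarchy],
            "dilation_radius_um": config.compartment.dilation_radius_um,
            "min_component": config.compartment.min_component,
            "r_max_um": config.spatial.r_max_um,
            "band_width_um": config.spatial.band_width_um,
            "interaction_radius_um": config.spatial.interaction_radius_um,
            "min_combined": config.spatial.min_combined,
            "border_correction": config.spatial.border_correction,
            "cutpoint_rule": str(config.cutpoint_rule),
            "seed": config.seed,
        },
        "inputs": {
            "cells": str(config.cells_path),
            "cohort": str(config.cohort_path),
        },
        "outputs": {str(p.relative_to(out)): sha256_file(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_report(run_dir: str | Path, out_dir: str | Path | None = None) -> Path:
    """Assemble machine-readable summary tables from a completed run."""
    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir else run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    feats_path = run_dir / "cohort_features.csv"
    surv_path = run_dir / "survival_results.csv"
    for p in (feats_path, surv_path):
        if not p.exists():
            raise FileNotFoundError(f"missing stage output: {p}")
    feats = pd.read_csv(feats_path) if feats_path.stat().st_size > 1 else pd.DataFrame()
    surv = pd.read_csv(surv_path)
    score_cols = [c for c in feats.columns if c.endswith("_gcross_score")]
    scores = feats[["sample_id", *score_cols]] if len(feats) else pd.DataFrame(columns=["sample_id"])
    scores.to_csv(out / "per_sample_scores.csv", index=False)
    surv.to_csv(out / "per_feature_survival.csv", index=False)
    totals = {
        "n_samples": int(len(scores)),
        "n_features": len(score_cols),
        "n_survival_rows": int(len(surv)),
    }
    (out / "report.json").write_text(json.dumps(totals, indent=2, sort_keys=True))
    return out
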