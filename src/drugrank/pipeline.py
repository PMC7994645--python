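"""End-to-end orchestration: panel -> markers -> D -> models -> rankings.

The pipeline enforces the train/validation discipline: marker discovery,
predictor selection, D normalization and model fitting see only training
cell lines; validation lines appear exclusively at prediction/evaluation
time, and a leakage guard verifies this on every run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from ._utils import derive_seed
from .discovery import DiscoveryParams, EMDRCatalog, build_catalog
from .distance import DistanceMatrix, apply_minmax, distance_matrix, fit_minmax, write_distance_matrix
from .ensemble import (
    DEFAULT_ROSTER,
    DrugModelEnsemble,
    partition_cell_lines,
    predict_responses,
    train_drug_models,
)
from .ranking import RankingReport, evaluate
from .selection import select_all, write_predictor_sets
from .simulate import PanelSpec, generate_panel


class LeakageError(RuntimeError):
    """Validation cell lines leaked into a training-side artifact."""


@dataclass
class RunConfig:
    """Every knob of the pipeline in one serializable record."""

    iqr_threshold: float = 0.15
    scale_axis: str = "cell_line"
    log2_transform: bool = False
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    min_markers: int = 5
    selection_alpha: float = 0.05
    selection_cap: int = 30
    selection_floor: int = 7
    partition_ratio: float = 0.8
    cv_folds: int = 10
    cv_repeats: int = 3
    roster: tuple = DEFAULT_ROSTER
    prediction_algorithms: tuple = ("random_forest", "consensus")
    top_k: int = 20
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roster"] = list(self.roster)
        d["prediction_algorithms"] = list(self.prediction_algorithms)
        return d

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    config: RunConfig
    responses: pio.DrugResponseTable          # scaled + IQR-filtered
    train_lines: list[str]
    validation_lines: list[str]
    catalog: EMDRCatalog
    distances: DistanceMatrix                 # raw D, all cell lines
    distances_norm: DistanceMatrix            # 0-1 normalized with training min-max
    predictor_sets: dict
    ensemble: DrugModelEnsemble
    predictions: dict[str, pd.DataFrame]      # algorithm -> drugs x validation lines
    reports: dict[str, RankingReport]
    manifest: dict


def check_no_leakage(manifest: dict) -> None:
    """Abort if any validation cell line reached a training-side stage."""
    validation = set(manifest["validation_lines"])
    for stage in ("discovery_lines", "selection_lines", "normalization_lines", "training_lines"):
        leaked = validation & set(manifest.get(stage, ()))
        if leaked:
            raise LeakageError(f"validation lines leaked into {stage}: {sorted(leaked)}")


def run_study(
    omics: pio.OmicsMatrix,
    responses: pio.DrugResponseTable,
    config: RunConfig | None = None,
    _inject_leakage: bool = False,
) -> StudyResult:
    """Run the full modeling study in memory and return all artifacts.

    ``_inject_leakage`` is a test hook that deliberately contaminates the
    discovery stage with a validation line so the leakage guard's abort
    path can be exercised.
    """
    config = config or RunConfig()
    seed = config.seed

    # --- normalize panel ---------------------------------------------------
    scaled = responses if responses.scaled else pio.scale_aac(responses, axis=config.scale_axis)
    scaled, iqr_report = pio.filter_drugs_by_iqr(scaled, config.iqr_threshold)
    # feature statistics on the cell-line scale, applied to every replicate:
    # discovery tests replicate-level values, D uses their line averages
    normed = omics if omics.normalized else pio.center_scale_features(
        omics, log2_transform=config.log2_transform, stats_from="cell_lines")
    averaged = pio.average_replicates(normed)

    # --- partition ---------------------------------------------------------
    lines = [c for c in averaged.sample_ids if c in set(scaled.cell_line_ids)]
    train_lines, validation_lines = partition_cell_lines(
        lines, scaled, ratio=config.partition_ratio, seed=derive_seed(seed, "partition"))

    discovery_lines = list(train_lines)
    if _inject_leakage and validation_lines:
        discovery_lines = discovery_lines + [validation_lines[0]]

    # --- EMDR discovery (training lines only, replicate-level contrasts) ---
    train_cols = [s for s in normed.sample_ids
                  if normed.replicate_map[s] in set(discovery_lines)]
    train_omics = normed.restrict_samples(train_cols)
    train_resp = scaled.restrict_cell_lines(discovery_lines)
    catalog = build_catalog(train_omics, train_resp, params=config.discovery,
                            seed=derive_seed(seed, "discovery"))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "train_lines": train_lines,
        "validation_lines": validation_lines,
        "discovery_lines": discovery_lines,
        "iqr_report": {"kept": iqr_report["kept"], "dropped": iqr_report["dropped"]},
        "skipped_drugs": catalog.skipped,
    }
    if not catalog.entries:
        raise RuntimeError("no drug yielded markers; cannot continue")

    # --- D metric ----------------------------------------------------------
    dm_all = distance_matrix(averaged, catalog, min_markers=config.min_markers)
    dm_train = DistanceMatrix(d=dm_all.d[train_lines])
    norm_params = fit_minmax(dm_train)
    dm_norm = apply_minmax(dm_all, norm_params)
    manifest["normalization_lines"] = train_lines

    # --- predictor selection (training lines only) -------------------------
    dm_norm_train = DistanceMatrix(d=dm_norm.d[train_lines], normalized=True)
    predictor_sets = select_all(dm_norm_train, train_resp, alpha=config.selection_alpha,
                                cap=config.selection_cap, floor=config.selection_floor)
    manifest["selection_lines"] = train_lines

    # --- model training ----------------------------------------------------
    ensemble = DrugModelEnsemble(
        predictor_sets=predictor_sets, norm_params=norm_params,
        train_lines=train_lines, validation_lines=validation_lines,
        seed=seed, roster=config.roster)
    training_lines_used: set[str] = set()
    model_skips: dict[str, str] = {}
    for drug, pset in predictor_sets.items():
        X = dm_norm.d.loc[pset.predictor_ids, train_lines].T
        y = scaled.aac.loc[drug, train_lines]
        keep = X.notna().all(axis=1) & y.notna()
        X, y = X[keep], y[keep]
        if len(y) < 10:
            model_skips[drug] = f"only {len(y)} complete training lines"
            continue
        training_lines_used.update(X.index)
        ensemble.models[drug] = train_drug_models(
            X, y, drug, roster=config.roster, cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats, seed=derive_seed(seed, "train"))
    manifest["training_lines"] = sorted(training_lines_used)
    manifest["model_skips"] = model_skips

    check_no_leakage(manifest)

    # --- prediction + evaluation on held-out lines -------------------------
    dm_val = DistanceMatrix(d=dm_norm.d[validation_lines], normalized=True,
                            norm_params=norm_params)
    predictions, reports = {}, {}
    val_measured = scaled.aac[validation_lines]
    for algo in config.prediction_algorithms:
        pred = predict_responses(ensemble, dm_val, algorithm=algo)
        predictions[algo] = pred
        reports[algo] = evaluate(pred, val_measured, top_k=config.top_k)
    manifest["summaries"] = {a: r.summary for a, r in reports.items()}

    return StudyResult(
        config=config, responses=scaled, train_lines=train_lines,
        validation_lines=validation_lines, catalog=catalog, distances=dm_all,
        distances_norm=dm_norm, predictor_sets=predictor_sets, ensemble=ensemble,
        predictions=predictions, reports=reports, manifest=manifest)


def run_pipeline(omics, responses, out_dir, config: RunConfig | None = None) -> Path:
    """File-level wrapper: run the study and write every stage artifact.

    Returns the run directory containing the manifest, catalog, D matrices,
    predictor sets, predictions and evaluation reports.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_study(omics, responses, config)

    result.catalog.to_json(out / "catalog.json")
    write_distance_matrix(result.distances, out / "distances.tsv")
    write_distance_matrix(result.distances_norm, out / "distances_norm.tsv")
    write_predictor_sets(result.predictor_sets, out / "predictors.json")
    for algo, pred in result.predictions.items():
        pred.to_csv(out / f"predictions_{algo}.tsv", sep="\t", index_label="drug_id")
        result.reports[algo].per_sample.to_csv(out / f"report_{algo}_per_sample.tsv",
                                               sep="\t", index=False)
    manifest = dict(result.manifest)
    pred_digest = hashlib.sha256()
    for algo in sorted(result.predictions):
        pred_digest.update(result.predictions[algo].round(12).to_csv().encode())
    manifest["prediction_digest"] = pred_digest.hexdigest()
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return out


def simulate_to_dir(spec: PanelSpec, out_dir) -> Path:
    """Generate a synthetic panel and write its TSVs + ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    omics, responses, truth = generate_panel(spec)
    pio.write_omics_matrix(omics, out / "omics.tsv")
    with open(out / "replicate_map.tsv", "w") as fh:
        fh.write("sample_id\tcell_line_id\n")
        for s, c in omics.replicate_map.items():
            fh.write(f"{s}\t{c}\n")
    pio.write_drug_response(responses, out / "responses.tsv")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump({
            "spec": asdict(truth.spec),
            "sensitivity_markers": truth.sensitivity_markers,
            "resistance_markers": truth.resistance_markers,
            "clusters": truth.clusters,
        }, fh, indent=1)
    truth.aac.to_csv(out / "true_aac.tsv", sep="\t", index_label="drug_id")
    return out
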