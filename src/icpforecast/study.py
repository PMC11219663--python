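"""End-to-end study driver.

``run_study`` composes every stage into the full replica: simulate (or
load) a cohort; apply the inclusion filters; extract the 11 features from
the first 6 h; label IH/SIH outcomes from the remaining monitoring period;
then, for each task, run the stratified 70/30 split, RFE-CV feature
selection, VIF screen, grid-searched forest fit with Youden cutoff,
held-out test metrics, whole-cohort fivefold cross-validation, and feature
importances; plus the two cohort group-comparison tables.  Everything is
deterministic from the master seed, and a manifest (config hash, seed,
package versions) accompanies every written bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import evalstats, io, labeling, rf_pipeline, signal_prep
from .config import RunConfig, dump_config
from .features import build_feature_table, featurize_patient
from .rf_pipeline import SplitSpec
from .simcohort import draw_baselines, draw_ground_truths, simulate_patient

__all__ = ["run_study", "prepare_cohort_table"]

log = logging.getLogger("icpforecast")


def _featurize_one(config: RunConfig, rec, baseline_row) -> tuple:
    """(exclusion_reason, features, label) for one patient."""
    es_raw = signal_prep.resample_epochs(rec, config.epoch_s)
    reason = labeling.exclusion_reason(
        es_raw,
        min_record_h=config.min_record_h,
        max_invalid_frac=config.artifact_max_invalid_frac,
        feature_window_h=config.feature_window_h,
        threshold_mmHg=config.ih_threshold_mmHg,
        early_ih_epoch_frac=config.early_ih_epoch_frac,
    )
    if reason is not None:
        return reason, None, None
    label = labeling.label_outcomes(
        es_raw,
        feature_window_h=config.feature_window_h,
        threshold_mmHg=config.ih_threshold_mmHg,
        ih_min_duration_min=config.ih_min_duration_min,
        sih_min_duration_min=config.sih_min_duration_min,
        min_record_h=config.min_record_h,
    )
    feats = featurize_patient(
        rec,
        baseline_row,
        feature_window_h=config.feature_window_h,
        epoch_s=config.epoch_s,
        smooth_span=config.smooth_span,
        prx_window_epochs=config.prx_window_epochs,
        rap_window_epochs=config.rap_window_epochs,
        cparams=config.complexity,
    )
    return None, feats, label


def prepare_cohort_table(config: RunConfig):
    """Simulate, filter, featurize and label the cohort.

    Recordings are generated one at a time and discarded after feature
    extraction to keep memory flat.  Returns ``(table, truths, excluded)``.
    """
    config.validate()
    truths = draw_ground_truths(config.sim)
    baselines = draw_baselines(config.sim, truths).set_index("patient_id")
    pairs, excluded, labels = [], [], []
    t0 = time.time()
    for truth in truths:
        rec = simulate_patient(config.sim, truth.patient_id, truth)
        base = baselines.loc[truth.patient_id].to_dict()
        reason, feats, label = _featurize_one(config, rec, base)
        if reason is not None:
            excluded.append((truth.patient_id, reason))
        else:
            pairs.append((feats, label))
            labels.append(label)
    log.info(
        "cohort: %d simulated, %d included, %d excluded (%.1f s)",
        len(truths), len(pairs), len(excluded), time.time() - t0,
    )
    table = build_feature_table(pairs)
    table.attrs["labels"] = labels
    return table, truths, excluded


def _evaluate_task(table: pd.DataFrame, task: str, config: RunConfig) -> dict:
    rf_cfg = replace(config.rf, seed=config.seed + (7 if task == "sih" else 3))
    split = SplitSpec(
        train_fraction=config.train_fraction, stratify_on=task, seed=config.seed + 11
    )
    train, test = rf_pipeline.stratified_split(table, split)
    selected = rf_pipeline.rfe_cv(train, task, rf_cfg)
    vif_report = (
        rf_pipeline.vif(train, selected) if len(selected) >= 2 else None
    )
    model = rf_pipeline.fit_rf(train, selected, rf_cfg, task=task)
    scores = rf_pipeline.predict_proba(model, test)
    y_test = test[task].to_numpy(dtype=int)
    test_metrics = evalstats.threshold_metrics(scores, y_test, model.cutoff)
    cv = evalstats.kfold_cv(table, task, rf_cfg, k=config.cv_folds, seed=config.seed + 13)
    imp = evalstats.importance(model, train)
    log.info(
        "task %s: %d features selected, test AUC %.3f, CV AUC %.3f",
        task, len(selected), test_metrics.auc, cv.summary().loc["auc", "mean"],
    )
    return {
        "task": task,
        "selected_features": selected,
        "vif": vif_report,
        "model": model,
        "test_metrics": test_metrics,
        "cv": cv,
        "importance": imp,
        "n_train": len(train),
        "n_test": len(test),
    }


def run_study(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Run the full study; optionally write a report bundle to ``out_dir``."""
    config.validate()
    table, truths, excluded = prepare_cohort_table(config)
    bundle: dict = {
        "config": config,
        "feature_table": table,
        "ground_truths": truths,
        "excluded": excluded,
        "group_compare": {
            task: evalstats.group_compare(table, task) for task in ("ih", "sih")
        },
        "tasks": {},
    }
    for task in ("ih", "sih"):
        bundle["tasks"][task] = _evaluate_task(table, task, config)
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    config: RunConfig = bundle["config"]
    table: pd.DataFrame = bundle["feature_table"]
    table.to_csv(out_dir / "features.csv", index=False, float_format="%.10g")
    labels = table.attrs.get("labels", [])
    io.write_labels_csv(labels, bundle["excluded"], out_dir / "labels.csv")
    for task, gc in bundle["group_compare"].items():
        gc.to_csv(out_dir / f"group_compare_{task}.csv", index=False)
    summary_lines = []
    for task, res in bundle["tasks"].items():
        res["importance"].to_csv(out_dir / f"importance_{task}.csv", index=False)
        res["cv"].summary().to_csv(out_dir / f"cv_{task}.csv")
        if res["vif"] is not None:
            res["vif"].values.rename("vif").to_csv(out_dir / f"vif_{task}.csv")
        m = res["test_metrics"]
        summary_lines.append(
            f"RF-{task.upper()}: features={res['selected_features']} "
            f"cutoff={res['model'].cutoff:.3f} "
            f"test accuracy={m.accuracy:.2f} sensitivity={m.sensitivity:.2f} "
            f"specificity={m.specificity:.2f} F1={m.f1:.2f} AUC={m.auc:.2f}"
        )
        rf_pipeline.save_model(res["model"], out_dir / f"model_{task}.joblib")
    (out_dir / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    config_text = dump_config(config, out_dir / "config.yaml")
    manifest = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "n_included": int(len(table)),
        "n_excluded": len(bundle["excluded"]),
        "versions": _versions(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _versions() -> dict:
    import sklearn
    import scipy

    from . import __version__

    return {
        "icpforecast": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }
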