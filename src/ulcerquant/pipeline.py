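"""End-to-end orchestration: quantify -> fuse -> screen -> fit -> evaluate.

One invocation produces one run directory containing the quantified feature
table, the fused cohort, per-task screened feature lists, metric reports,
and a manifest with the config hash and seeds.  Re-running the same config
reproduces every number exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import io as uio
from .config import PipelineConfig
from .prognosis import (
    CohortError,
    cohort_feature_columns,
    cross_validate,
    evaluate,
    fit_prognostic_model,
    fuse_features,
    lasso_screen,
    split_cohort,
)
from .quantify import quantify_eye

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage context
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


@_stage("quantify")
def quantify_stage(config: PipelineConfig) -> pd.DataFrame:
    manifest = uio.read_manifest(config.manifest_csv)
    rows = []
    for _, row in manifest.iterrows():
        eye = uio.read_eye_masks(config.masks_dir, row, pupil_policy=config.pupil_policy)
        qf = quantify_eye(
            eye, abscess_mode=config.abscess_mode, occlusion_target=config.occlusion_target
        )
        out = qf.to_row()
        if "patient_id" in row:
            out["patient_id"] = row["patient_id"]
        rows.append(out)
    return pd.DataFrame(rows)


@_stage("fuse")
def fuse_stage(config: PipelineConfig, features: pd.DataFrame) -> pd.DataFrame:
    clinical = uio.read_clinical_csv(config.clinical_csv)
    outcomes = uio.read_outcomes_csv(config.outcomes_csv)
    return fuse_features(features, clinical, outcomes=outcomes, rule=config.fusion_rule)


@_stage("model")
def model_stage(config: PipelineConfig, cohort: pd.DataFrame, task: str) -> dict:
    train, val = split_cohort(
        cohort, task, ratio=config.split_ratio, seed=config.stage_seed("split")
    )
    selected = lasso_screen(train, task, seed=config.stage_seed("screen"))
    feats = selected or cohort_feature_columns(cohort)
    model = fit_prognostic_model(
        train,
        task,
        feats,
        algorithm=config.algorithm,
        params=config.boost_params,
        seed=config.stage_seed("model"),
    )
    report_train = evaluate(
        model,
        train,
        task,
        threshold=config.threshold,
        n_boot=config.bootstrap_replicates,
        seed=config.stage_seed("bootstrap"),
    )
    report_val = evaluate(
        model,
        val,
        task,
        threshold=config.threshold,
        n_boot=config.bootstrap_replicates,
        seed=config.stage_seed("bootstrap"),
    )
    return {
        "selected_features": feats,
        "screened": bool(selected),
        "train": report_train.to_dict(config.round_digits),
        "validation": report_val.to_dict(config.round_digits),
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    run_dir = Path(config.out_dir) / f"run_{config.content_hash()}"
    run_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    features = quantify_stage(config)
    features.to_csv(run_dir / "features.csv", index=False)

    cohort = fuse_stage(config, features)
    cohort.to_csv(run_dir / "cohort.csv", index=False)

    reports = {}
    for task in config.tasks:
        try:
            reports[task] = model_stage(config, cohort, task)
        except PipelineStageError as err:
            if isinstance(err.cause, CohortError):
                log.warning("task %s skipped: %s", task, err.cause)
                reports[task] = {"skipped": str(err.cause)}
            else:
                raise
        for split_name in ("train", "validation"):
            if split_name in reports[task]:
                uio.write_report_json(
                    run_dir / f"report_{task}_{split_name}.json",
                    reports[task][split_name],
                )

    manifest = {
        "config": asdict(config),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in ("split", "screen", "model", "bootstrap")},
        "n_eyes": int(len(features)),
        "n_patients": int(len(cohort)),
        "elapsed_s": round(time.time() - t0, 3),
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    uio.write_json(run_dir / "reports.json", reports)
    return run_dir


def crossval_pipeline(config: PipelineConfig, cohort: pd.DataFrame, task: str) -> dict:
    """Nested-screened k-fold CV for one task, as a JSON-ready payload."""
    reports, mean = cross_validate(
        cohort,
        task,
        algorithm=config.algorithm,
        k=config.cv_folds,
        seed=config.stage_seed("split"),
        params=config.boost_params,
        threshold=config.threshold,
    )
    return {
        "folds": [r.to_dict(config.round_digits) for r in reports],
        "mean": {k: (None if v is None else round(v, 4)) for k, v in mean.items()},
    }
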