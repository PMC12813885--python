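"""End-to-end workflow: develop -> calibrate -> deploy.

``run_pipeline`` wires the stages together: generate a phantom cohort, train
the classifier on balanced epochs, run MC-dropout inference on validation
data, calibrate per-structure uncertainty thresholds at the target
sensitivity, predict on a frozen balanced test set, apply the accept/flag
policy and emit metric reports.  Every stage draws its seed deterministically
from one master seed by stage-name hashing, so re-running a config reproduces
every artifact bit-for-bit and adding a stage never shifts another stage's
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import (
    DEFAULT_TARGET_RECALL,
    ThresholdTable,
    apply_policy,
    binned_performance,
    calibrate_thresholds,
)
from .data import (
    StructureCatalogue,
    acceptable_pools,
    build_balanced_set,
    build_epoch,
    write_test_manifest,
)
from .evaluate import compute_metrics, deployment_report
from .model import ContourQualityNet, ModelConfig, TrainConfig, save_checkpoint, train
from .phantom import PhantomConfig, generate_cohort, write_cohort
from .uncertainty import DEFAULT_T, MCPrediction, PredictionRecord, predict_records

logger = logging.getLogger("contourqa")

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "records_to_csv", "records_from_csv"]


def scaled_experiment_config(seed: int = 0) -> "RunConfig":
    """Desk-scale study conditions: 100/20/20 patients, 3 structures, the
    small backbone trained 20 epochs at a short-schedule learning rate, and
    T=10 MC passes.  Used by the synthetic end-to-end evaluation."""
    return RunConfig(
        train=TrainConfig(epochs=20, initial_lr=3e-3),
        n_train=100,
        n_val=20,
        n_test=20,
        T=10,
        seed=seed,
        write_images=False,
    )


def smoke_config(seed: int = 0) -> "RunConfig":
    """Minutes-scale wiring check: tiny cohort, few epochs, T=5."""
    return RunConfig(
        phantom=PhantomConfig(slices_per_patient=(2, 2)),
        train=TrainConfig(epochs=2, initial_lr=3e-3),
        n_train=4,
        n_val=2,
        n_test=2,
        T=5,
        seed=seed,
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31, independent across stages."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    n_train: int = 100
    n_val: int = 20
    n_test: int = 20
    T: int = DEFAULT_T
    target_recall: float = DEFAULT_TARGET_RECALL
    recall_overrides: dict = field(default_factory=dict)
    seed: int = 0
    write_images: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "phantom" in raw:
            ph = dict(raw["phantom"])
            for key in ("slices_per_patient", "foreground_means"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            if "semi_axis_ranges" in ph:
                ph["semi_axis_ranges"] = tuple(tuple(r) for r in ph["semi_axis_ranges"])
            kwargs["phantom"] = PhantomConfig(**ph)
        if "model" in raw:
            m = dict(raw["model"])
            if "fc_sizes" in m:
                m["fc_sizes"] = tuple(m["fc_sizes"])
            kwargs["model"] = ModelConfig(**m)
        if "train" in raw:
            kwargs["train"] = TrainConfig(**raw["train"])
        for key in ("n_train", "n_val", "n_test", "T", "target_recall",
                    "recall_overrides", "seed", "write_images"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def with_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(self, seed=seed)


def records_to_csv(records, path) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "structure": r.structure,
            "true_label": r.true_label,
            "per_pass_probs": json.dumps(list(r.prediction.per_pass_probs)),
            "mean_prob": r.prediction.mean_prob,
            "entropy": r.prediction.entropy,
            "predicted_label": r.prediction.predicted_label,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")  # bit-exact round trip
    return df


def records_from_csv(path) -> list[PredictionRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for row in df.itertuples():
        probs = tuple(json.loads(row.per_pass_probs))
        records.append(
            PredictionRecord(
                sample_id=row.sample_id,
                structure=row.structure,
                true_label=int(row.true_label),
                prediction=MCPrediction(
                    per_pass_probs=probs,
                    mean_prob=float(row.mean_prob),
                    entropy=float(row.entropy),
                    predicted_label=int(row.predicted_label),
                ),
            )
        )
    return records


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _report_to_jsonable(report) -> dict:
    def conv(metrics):
        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in metrics.items()}

    return {"mode": report.mode, "overall": conv(report.overall),
            "per_structure": {k: conv(v) for k, v in report.per_structure.items()}}


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the full workflow; returns a dict of in-memory results and paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    stage = "phantom"
    logger.info("stage %s: generating cohort %d/%d/%d", stage,
                config.n_train, config.n_val, config.n_test)
    phantom_cfg = dataclasses.replace(config.phantom, seed=stage_seed(config.seed, stage))
    train_pat, val_pat, test_pat = generate_cohort(
        phantom_cfg, config.n_train, config.n_val, config.n_test
    )
    catalogue = StructureCatalogue(names=phantom_cfg.structure_names)
    if config.write_images:
        write_cohort(out / "phantom", phantom_cfg,
                     {"train": train_pat, "val": val_pat, "test": test_pat})
        artifacts["phantom_manifest"] = out / "phantom" / "manifest.csv"

    train_pools = acceptable_pools(train_pat, catalogue)
    val_pools = acceptable_pools(val_pat, catalogue)
    test_pools = acceptable_pools(test_pat, catalogue)

    stage = "train"
    model_cfg = dataclasses.replace(
        config.model,
        structure_code_length=len(catalogue),
        image_size=phantom_cfg.image_size,
    )
    train_cfg = dataclasses.replace(config.train, seed=stage_seed(config.seed, stage))
    model = ContourQualityNet(model_cfg, rng=np.random.default_rng(stage_seed(config.seed, "init")))
    val_balanced = build_balanced_set(val_pools, seed=stage_seed(config.seed, "val_set"))
    logger.info("stage %s: %d train slices, %d balanced val samples",
                stage, sum(len(v) for v in train_pools.values()), len(val_balanced))
    model, log = train(model, lambda rng: build_epoch(train_pools, rng), val_balanced, train_cfg)
    pd.DataFrame(log).to_csv(out / "training_log.csv", index=False)
    save_checkpoint(out / "checkpoint.npz", model, catalogue, train_cfg)
    artifacts["training_log"] = out / "training_log.csv"
    artifacts["checkpoint"] = out / "checkpoint.npz"

    stage = "val_predict"
    val_records = predict_records(model, val_balanced, T=config.T,
                                  seed=stage_seed(config.seed, stage))
    records_to_csv(val_records, out / "val_predictions.csv")
    artifacts["val_predictions"] = out / "val_predictions.csv"

    stage = "calibrate"
    thresholds = calibrate_thresholds(
        val_records, target_recall=config.target_recall,
        overrides=config.recall_overrides,
    )
    thresholds.to_json(out / "thresholds.json")
    artifacts["thresholds"] = out / "thresholds.json"
    logger.info("stage %s: %s", stage,
                {k: round(v.tau, 3) for k, v in thresholds.entries.items()})

    stage = "test_predict"
    test_set = build_balanced_set(test_pools, seed=stage_seed(config.seed, "test_set"))
    write_test_manifest(out / "test_manifest.csv", test_set)
    test_records = predict_records(model, test_set, T=config.T,
                                   seed=stage_seed(config.seed, stage))
    records_to_csv(test_records, out / "test_predictions.csv")
    artifacts["test_manifest"] = out / "test_manifest.csv"
    artifacts["test_predictions"] = out / "test_predictions.csv"

    stage = "qa"
    decisions = apply_policy(test_records, thresholds)
    pd.DataFrame([dataclasses.asdict(d) for d in decisions]).to_csv(
        out / "decisions.csv", index=False
    )
    artifacts["decisions"] = out / "decisions.csv"
    n_auto = sum(d.decision == "auto_accept_prediction" for d in decisions)
    logger.info("stage %s: %d/%d auto-accepted", stage, n_auto, len(decisions))

    stage = "evaluate"
    report = compute_metrics(test_records, mode="mean_prob")
    per_pass = compute_metrics(test_records, mode="per_pass")
    deploy = deployment_report(decisions, test_records)
    bins = binned_performance(test_records)
    payload = {
        "mean_prob": _report_to_jsonable(report),
        "per_pass": _report_to_jsonable(per_pass),
        "deployment": deploy.to_dict(orient="records"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    bins.to_csv(out / "uncertainty_bins.csv", index=False)
    artifacts["report"] = out / "report.json"
    artifacts["uncertainty_bins"] = out / "uncertainty_bins.csv"

    manifest = {
        "version": __version__,
        "master_seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in
                        ("phantom", "init", "train", "val_set", "val_predict",
                         "calibrate", "test_set", "test_predict", "qa", "evaluate")},
        "artifacts": {k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                      for k, p in artifacts.items()},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "model": model,
        "catalogue": catalogue,
        "training_log": log,
        "val_records": val_records,
        "thresholds": thresholds,
        "test_records": test_records,
        "decisions": decisions,
        "metrics": report,
        "metrics_per_pass": per_pass,
        "deployment": deploy,
        "bins": bins,
        "out_dir": out,
    }
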