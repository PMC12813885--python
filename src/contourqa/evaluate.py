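"""Classification metrics and deployment-style reports.

Metrics follow the standard QA evaluation: accuracy, precision, recall, F1
and ROC AUC with revision-required as the positive class, thresholding
probabilities at the fixed 0.5 quality cut.  Two modes are provided:

* ``mean_prob`` — one value per metric, computed from the MC-mean probability;
* ``per_pass`` — each metric computed separately per stochastic forward pass
  (thresholding/ranking that pass's probabilities) and reported as
  mean +/- standard deviation across the T passes.

``deployment_report`` restricts the metrics to the auto-accepted subset under
a threshold policy and reports the retained population fraction per structure.
Overall rows pool all slices rather than averaging per-structure metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .calibrate import AUTO, Decision
from .uncertainty import PredictionRecord

__all__ = ["MetricsReport", "compute_metrics", "deployment_report", "format_percent"]

METRICS = ("accuracy", "recall", "precision", "f1", "auc")


def _binary_metrics(true: np.ndarray, scores: np.ndarray) -> dict[str, Optional[float]]:
    pred = (scores >= 0.5).astype(int)
    out = {
        "accuracy": float(accuracy_score(true, pred)),
        "recall": float(recall_score(true, pred, zero_division=0)),
        "precision": float(precision_score(true, pred, zero_division=0)),
        "f1": float(f1_score(true, pred, zero_division=0)),
    }
    if len(np.unique(true)) < 2:
        warnings.warn("single-class input: AUC is undefined and reported as absent")
        out["auc"] = None
    else:
        out["auc"] = float(roc_auc_score(true, scores))
    return out


@dataclass(frozen=True)
class MetricsReport:
    mode: str  # "mean_prob" or "per_pass"
    overall: dict
    per_structure: dict[str, dict]

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, percentages to one decimal place."""
        rows = []
        for name, metrics in [("overall", self.overall)] + sorted(self.per_structure.items()):
            row = {"structure": name}
            for m in METRICS:
                v = metrics.get(m)
                if v is None:
                    row[m] = ""
                elif self.mode == "per_pass":
                    row[m] = f"{100 * v[0]:.1f} +/- {100 * v[1]:.1f}"
                else:
                    row[m] = f"{100 * v:.1f}"
            rows.append(row)
        return pd.DataFrame(rows)


def format_percent(x: float) -> str:
    return f"{100 * x:.1f}"


def _scores(records: Sequence[PredictionRecord], mode: str) -> np.ndarray:
    if mode == "mean_prob":
        return np.array([[r.prediction.mean_prob for r in records]])
    if mode == "per_pass":
        T = records[0].prediction.T
        if any(r.prediction.T != T for r in records):
            raise ValueError("per-pass mode needs a common T across records")
        return np.array([[r.prediction.per_pass_probs[t] for r in records] for t in range(T)])
    raise ValueError(f"unknown mode {mode!r}")


def _metrics_for(records: Sequence[PredictionRecord], mode: str) -> dict:
    true = np.array([r.true_label for r in records])
    score_rows = _scores(records, mode)
    per_row = [_binary_metrics(true, s) for s in score_rows]
    if mode == "mean_prob":
        return per_row[0]
    out = {}
    for m in METRICS:
        vals = [d[m] for d in per_row]
        if any(v is None for v in vals):
            out[m] = None
        else:
            out[m] = (float(np.mean(vals)), float(np.std(vals)))
    return out


def compute_metrics(records: Sequence[PredictionRecord], mode: str = "mean_prob") -> MetricsReport:
    """Overall and per-structure metrics; positive class = revision required."""
    if len(records) == 0:
        raise ValueError("no predictions to evaluate")
    structures = sorted({r.structure for r in records})
    per_structure = {}
    for name in structures:
        group = [r for r in records if r.structure == name]
        per_structure[name] = _metrics_for(group, mode)
    return MetricsReport(
        mode=mode,
        overall=_metrics_for(records, mode),
        per_structure=per_structure,
    )


def deployment_report(
    decisions: Sequence[Decision], records: Sequence[PredictionRecord]
) -> pd.DataFrame:
    """Per-structure metrics restricted to auto-accepted samples.

    One row per structure plus an ``overall`` row: accuracy and recall on the
    auto subset (NaN with a warning if a structure has nothing auto-accepted)
    and the auto-accepted population fraction.
    """
    by_id = {r.sample_id: r for r in records}
    missing = [d.sample_id for d in decisions if d.sample_id not in by_id]
    if missing:
        raise ValueError(f"decisions reference unknown sample ids, e.g. {missing[0]!r}")
    auto_ids = {d.sample_id for d in decisions if d.decision == AUTO}
    rows = []
    structures = sorted({d.structure for d in decisions})
    for name in structures + ["overall"]:
        group = [d for d in decisions if d.structure == name or name == "overall"]
        auto = [by_id[d.sample_id] for d in group if d.sample_id in auto_ids]
        row = {"structure": name, "n": len(group), "n_auto": len(auto),
               "population_auto": len(auto) / len(group) if group else np.nan}
        if auto:
            true = np.array([r.true_label for r in auto])
            pred = np.array([r.prediction.predicted_label for r in auto])
            row["accuracy_auto"] = float((pred == true).mean())
            pos = true == 1
            row["recall_auto"] = float(((pred == 1) & pos).sum() / pos.sum()) if pos.any() else np.nan
        else:
            warnings.warn(f"structure {name!r}: no auto-accepted samples; metrics absent")
            row["accuracy_auto"] = np.nan
            row["recall_auto"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
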