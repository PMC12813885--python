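"""Recall-vs-uncertainty calibration and the accept/flag decision policy.

On a validation cohort, predictions are sorted by ascending uncertainty and
the cumulative recall for the revision-required class is computed across the
ordered set.  The uncertainty threshold tau for a structure is the uncertainty
of the first point at which cumulative recall drops below the clinical target
(default 98% sensitivity); predictions with uncertainty strictly below tau are
trusted for automated QA, all others are flagged for clinician review.  If the
curve never drops below the target, tau = 1.0 and everything is auto-accepted.

Conventions (stated once, used throughout): cumulative recall is the
sensitivity *within* the low-uncertainty prefix; before the first
revision-required sample enters the prefix it is vacuously 1; sorting ties are
broken by sample id; a sample whose uncertainty equals tau is flagged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .uncertainty import PredictionRecord

__all__ = [
    "DEFAULT_TARGET_RECALL",
    "DEFAULT_N_BINS",
    "CalibrationCurve",
    "ThresholdEntry",
    "ThresholdTable",
    "Decision",
    "build_curve",
    "select_threshold",
    "calibrate_thresholds",
    "apply_policy",
    "binned_performance",
]

DEFAULT_TARGET_RECALL = 0.98
DEFAULT_N_BINS = 80

AUTO = "auto_accept_prediction"
FLAG = "flag_for_review"


@dataclass(frozen=True)
class CalibrationCurve:
    """Predictions ordered by ascending uncertainty with prefix statistics."""

    uncertainties: np.ndarray  # non-decreasing
    cumulative_recall: np.ndarray  # sensitivity within each prefix
    population_fraction: np.ndarray  # (i + 1) / n

    def __len__(self) -> int:
        return len(self.uncertainties)


def _unpack(records: Sequence[PredictionRecord]):
    u = np.array([r.prediction.entropy for r in records])
    true = np.array([r.true_label for r in records])
    pred = np.array([r.prediction.predicted_label for r in records])
    ids = [r.sample_id for r in records]
    return u, true, pred, ids


def build_curve(records: Sequence[PredictionRecord]) -> CalibrationCurve:
    """Cumulative revision-required recall over the ascending-uncertainty order.

    Ties in uncertainty are broken by sample id (stable), so the curve is
    reproducible regardless of input order.
    """
    if len(records) == 0:
        raise ValueError("cannot build a calibration curve from zero predictions")
    u, true, pred, ids = _unpack(records)
    if true.sum() == 0:
        raise ValueError("no revision-required samples; recall is undefined")
    order = np.lexsort((np.array(ids), u))
    u, true, pred = u[order], true[order], pred[order]
    n = len(records)
    pos = np.cumsum(true)
    tp = np.cumsum(true * (pred == 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(pos > 0, tp / np.maximum(pos, 1), 1.0)  # vacuous prefix -> 1
    return CalibrationCurve(
        uncertainties=u,
        cumulative_recall=recall,
        population_fraction=np.arange(1, n + 1) / n,
    )


def select_threshold(curve: CalibrationCurve, target_recall: float = DEFAULT_TARGET_RECALL) -> float:
    """Uncertainty of the first point whose cumulative recall drops below target.

    Returns 1.0 (accept everything) if the curve never drops below the target.
    By construction the strict-prefix {uncertainty < tau} then satisfies the
    target sensitivity on the calibration set itself.
    """
    if not (0.0 < target_recall <= 1.0):
        raise ValueError("target_recall must be in (0, 1]")
    if len(curve) == 0:
        raise ValueError("empty calibration curve")
    below = curve.cumulative_recall < target_recall
    if not below.any():
        return 1.0
    return float(curve.uncertainties[int(np.argmax(below))])


@dataclass(frozen=True)
class ThresholdEntry:
    tau: float
    target_recall: float
    val_recall_below_tau: float
    population_below_tau: float


@dataclass(frozen=True)
class ThresholdTable:
    entries: dict[str, ThresholdEntry]

    def tau(self, structure: str) -> float:
        if structure not in self.entries:
            raise KeyError(f"no uncertainty threshold for structure {structure!r}")
        return self.entries[structure].tau

    def to_json(self, path=None) -> str:
        payload = {name: asdict(e) for name, e in self.entries.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "ThresholdTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(entries={k: ThresholdEntry(**v) for k, v in payload.items()})


def _recall_below(records: Sequence[PredictionRecord], tau: float) -> float:
    u, true, pred, _ = _unpack(records)
    keep = u < tau
    pos = (true == 1) & keep
    if pos.sum() == 0:
        return 1.0  # vacuous: no revision-required sample accepted
    return float(((pred == 1) & pos).sum() / pos.sum())


def calibrate_thresholds(
    records: Sequence[PredictionRecord],
    target_recall: float = DEFAULT_TARGET_RECALL,
    per_structure: bool = True,
    overrides: Optional[dict[str, float]] = None,
) -> ThresholdTable:
    """Per-structure thresholds from validation predictions.

    ``overrides`` maps structure names to stricter (or looser) recall targets,
    e.g. 1.0 for a treatment target where missed errors are unacceptable.
    With ``per_structure=False`` one pooled curve sets a common tau (useful
    for very small cohorts).
    """
    overrides = overrides or {}
    structures = sorted({r.structure for r in records})
    entries: dict[str, ThresholdEntry] = {}
    if not per_structure:
        pooled_curve = build_curve(records)
    for name in structures:
        target = overrides.get(name, target_recall)
        group = [r for r in records if r.structure == name]
        curve = build_curve(group) if per_structure else pooled_curve
        tau = select_threshold(curve, target)
        u = np.array([r.prediction.entropy for r in group])
        entries[name] = ThresholdEntry(
            tau=tau,
            target_recall=target,
            val_recall_below_tau=_recall_below(group, tau),
            population_below_tau=float((u < tau).mean()),
        )
    return ThresholdTable(entries=entries)


@dataclass(frozen=True)
class Decision:
    sample_id: str
    structure: str
    mean_prob: float
    entropy: float
    predicted_label: int
    decision: str  # AUTO or FLAG


def apply_policy(
    records: Sequence[PredictionRecord], thresholds: ThresholdTable
) -> list[Decision]:
    """Auto-accept a prediction iff its uncertainty is strictly below tau."""
    decisions = []
    for r in records:
        tau = thresholds.tau(r.structure)
        decisions.append(
            Decision(
                sample_id=r.sample_id,
                structure=r.structure,
                mean_prob=r.prediction.mean_prob,
                entropy=r.prediction.entropy,
                predicted_label=r.prediction.predicted_label,
                decision=AUTO if r.prediction.entropy < tau else FLAG,
            )
        )
    return decisions


def binned_performance(
    records: Sequence[PredictionRecord], n_bins: int = DEFAULT_N_BINS
) -> pd.DataFrame:
    """Accuracy and revision-required recall within uniform uncertainty bins.

    [0, 1] is split into ``n_bins`` equal bins (uncertainty 1.0 falls in the
    last); empty bins are omitted and bins without revision-required members
    report recall as NaN.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    u, true, pred, _ = _unpack(records)
    bin_index = np.minimum((u * n_bins).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = bin_index == b
        if not sel.any():
            continue
        pos = sel & (true == 1)
        recall = float(((pred == 1) & pos).sum() / pos.sum()) if pos.any() else np.nan
        rows.append(
            {
                "bin": b,
                "n": int(sel.sum()),
                "mean_uncertainty": float(u[sel].mean()),
                "accuracy": float((pred[sel] == true[sel]).mean()),
                "recall": recall,
            }
        )
    if not rows:
        warnings.warn("no populated uncertainty bins")
    return pd.DataFrame(rows)
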