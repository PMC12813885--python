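"""Monte-Carlo dropout inference and normalized-entropy uncertainty.

Keeping the classifier's dropout units active at test time and running T
stochastic forward passes draws T weight samples from the variational
posterior; the mean of the T predicted probabilities approximates the
predictive distribution, and the normalized Shannon entropy of that mean,

    H(p) = -[p log p + (1 - p) log(1 - p)] / log 2,

is the uncertainty score (0 = fully confident, 1 = maximally uncertain).
The hard QA label applies the fixed 0.5 quality threshold to the mean
probability.  T defaults to 30 passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import SliceSample
from .model import ContourQualityNet

__all__ = [
    "DEFAULT_T",
    "MCPrediction",
    "PredictionRecord",
    "normalized_entropy",
    "mc_predict",
    "mc_predict_batch",
]

DEFAULT_T = 30
QUALITY_THRESHOLD = 0.5
LABEL_NAMES = ("acceptable", "revision_required")

_EPS = 1e-12  # clamp inside the log only; reported probabilities stay exact


def normalized_entropy(p_hat) -> np.ndarray | float:
    """Binary Shannon entropy of ``p_hat``, normalized to [0, 1].

    Uses the limit convention 0*log(0) = 0, so H(0) = H(1) = 0 exactly and
    H(0.5) = 1 exactly.  Accepts scalars or arrays; raises on values outside
    [0, 1].
    """
    p = np.asarray(p_hat, dtype=np.float64)
    if np.any((p < 0.0) | (p > 1.0)):
        raise ValueError("p_hat must lie in [0, 1]")
    # 0*log(0) := 0 exactly: each term vanishes where its probability does
    term_p = np.where(p > 0.0, p * np.log(np.clip(p, _EPS, None)), 0.0)
    term_q = np.where(p < 1.0, (1.0 - p) * np.log(np.clip(1.0 - p, _EPS, None)), 0.0)
    h = np.clip(-(term_p + term_q) / np.log(2.0), 0.0, 1.0)
    if np.isscalar(p_hat) or np.ndim(p_hat) == 0:
        return float(h)
    return h


@dataclass(frozen=True)
class MCPrediction:
    """Result of T stochastic forward passes on one sample."""

    per_pass_probs: tuple[float, ...]
    mean_prob: float
    entropy: float
    predicted_label: int  # 1 = revision required (mean_prob >= 0.5)

    @property
    def T(self) -> int:
        return len(self.per_pass_probs)

    @property
    def predicted_label_name(self) -> str:
        return LABEL_NAMES[self.predicted_label]


@dataclass(frozen=True)
class PredictionRecord:
    """An MC prediction tied back to its sample's identity and true label."""

    sample_id: str
    structure: str
    true_label: int
    prediction: MCPrediction


def _pass_rng(seed: int, t: int) -> np.random.Generator:
    # counter-based splitting: pass t's stream depends only on (seed, t)
    return np.random.default_rng([seed, t])


def _finalize(per_pass: np.ndarray) -> MCPrediction:
    mean_prob = float(np.mean(per_pass))
    return MCPrediction(
        per_pass_probs=tuple(float(p) for p in per_pass),
        mean_prob=mean_prob,
        entropy=float(normalized_entropy(mean_prob)),
        predicted_label=int(mean_prob >= QUALITY_THRESHOLD),
    )


def mc_predict(
    model: ContourQualityNet, sample: SliceSample, T: int = DEFAULT_T, seed: int = 0
) -> MCPrediction:
    """Run exactly T dropout-active forward passes on one sample."""
    preds = mc_predict_batch(model, [sample], T=T, seed=seed)
    return preds[0]


def mc_predict_batch(
    model: ContourQualityNet,
    samples: Sequence[SliceSample],
    T: int = DEFAULT_T,
    seed: int = 0,
    batch_size: int = 256,
) -> list[MCPrediction]:
    """MC-dropout inference over many samples with shared per-pass RNG streams."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if not model.has_dropout:
        raise ValueError("model has no dropout units; MC uncertainty is undefined")
    n = len(samples)
    probs = np.empty((T, n))
    for t in range(T):
        rng = _pass_rng(seed, t)
        for i in range(0, n, batch_size):
            chunk = samples[i:i + batch_size]
            images = np.stack([s.image for s in chunk])
            masks = np.stack([s.mask for s in chunk]).astype(np.float64)
            codes = np.stack([s.structure_code for s in chunk])
            probs[t, i:i + len(chunk)] = model.predict_proba(images, masks, codes,
                                                             dropout_rng=rng)
    return [_finalize(probs[:, i]) for i in range(n)]


def predict_records(
    model: ContourQualityNet,
    samples: Sequence[SliceSample],
    T: int = DEFAULT_T,
    seed: int = 0,
) -> list[PredictionRecord]:
    """Convenience wrapper pairing MC predictions with sample identities."""
    preds = mc_predict_batch(model, samples, T=T, seed=seed)
    return [
        PredictionRecord(
            sample_id=s.sample_id,
            structure=s.structure,
            true_label=s.label,
            prediction=p,
        )
        for s, p in zip(samples, preds)
    ]
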