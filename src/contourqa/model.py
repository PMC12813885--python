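"""The structure-coded contour-quality classifier and its training loop.

The network is a residual CNN over a two-channel input (image slice stacked
with the binary contour mask) whose pooled features are concatenated with a
one-hot structure code before a fully connected head.  Every fully connected
layer is preceded by a dropout unit (rate 0.1 by default); keeping those
dropout units active at inference is what enables Monte-Carlo uncertainty
estimation downstream.  The single sigmoid output is the probability that the
contour requires revision; 0.5 is the fixed quality threshold.

Training uses binary cross-entropy with Adam, an initial learning rate of
1e-4 cut to 20% every 100 epochs, batch size 64, and per-structure balanced
epochs supplied by a caller-provided epoch builder.  The best checkpoint by
validation accuracy (at threshold 0.5) is retained.

Two backbones are configured: ``resnet34_style`` (stages of 3/4/6/3 blocks at
64/128/256/512 channels) and ``small_resnet`` (three downsampling stages at
16/32/64 channels) for desk-scale experiments.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np

from . import nn
from .data import SliceSample, StructureCatalogue

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "ContourQualityNet",
    "learning_rate_at",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

BACKBONES = {
    # stem: (channels, stride); stages: list of (channels, n_blocks, first stride)
    "small_resnet": {"stem": (16, 2), "stages": [(32, 1, 2), (64, 1, 2)]},
    "resnet34_style": {
        "stem": (64, 2),
        "stages": [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2)],
    },
}


@dataclass(frozen=True)
class ModelConfig:
    backbone: str = "small_resnet"
    in_channels: int = 2
    fc_sizes: tuple[int, ...] = (32,)
    dropout_rate: float = 0.1
    structure_code_length: int = 3
    image_size: int = 64

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if not (0.0 < self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in (0, 1)")
        if self.structure_code_length < 1:
            raise ValueError("structure_code_length must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    initial_lr: float = 1e-4
    lr_decay: float = 0.2  # rate is multiplied by this ...
    lr_decay_every: int = 100  # ... every this many epochs
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def learning_rate_at(config: TrainConfig, epoch: int) -> float:
    """Step schedule: lr * decay^(epoch // decay_every)."""
    return config.initial_lr * config.lr_decay ** (epoch // config.lr_decay_every)


class ContourQualityNet:
    """Two-channel residual CNN with a structure-conditioned MC-dropout head."""

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        arch = BACKBONES[config.backbone]
        stem_c, stem_s = arch["stem"]
        self.stem_conv = nn.Conv2d(config.in_channels, stem_c, 3, stem_s, 1, rng)
        self.stem_bn = nn.BatchNorm2d(stem_c)
        self.stem_relu = nn.ReLU()
        self.blocks: list[nn.ResidualBlock] = []
        cin = stem_c
        for cout, n_blocks, stride in arch["stages"]:
            for b in range(n_blocks):
                self.blocks.append(nn.ResidualBlock(cin, cout, stride if b == 0 else 1, rng))
                cin = cout
        self.pool = nn.GlobalAvgPool()
        self.feature_dim = cin

        # head: every Dense is preceded by a Dropout unit
        self.head: list = []
        nin = self.feature_dim + config.structure_code_length
        for width in config.fc_sizes:
            self.head.append(nn.Dropout(config.dropout_rate))
            self.head.append(nn.Dense(nin, width, rng))
            self.head.append(nn.ReLU())
            nin = width
        self.head.append(nn.Dropout(config.dropout_rate))
        self.head.append(nn.Dense(nin, 1, rng))

    # -- plumbing ----------------------------------------------------------

    def parameters(self) -> list[nn.Parameter]:
        params = self.stem_conv.parameters() + self.stem_bn.parameters()
        for block in self.blocks:
            params += block.parameters()
        for layer in self.head:
            params += layer.parameters()
        return params

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.parameters()]
        for bn in self._batchnorms():
            arrays += [bn.running_mean.copy(), bn.running_var.copy()]
        return arrays

    def load_state(self, arrays: Sequence[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays):
            p.value[...] = a
        rest = arrays[len(params):]
        for bn, (m, v) in zip(self._batchnorms(), zip(rest[::2], rest[1::2])):
            bn.running_mean[...] = m
            bn.running_var[...] = v

    def _batchnorms(self) -> list[nn.BatchNorm2d]:
        bns = [self.stem_bn]
        for block in self.blocks:
            bns += [block.bn1, block.bn2]
            if block.proj is not None:
                bns.append(block.bn_proj)
        return bns

    @property
    def has_dropout(self) -> bool:
        return any(isinstance(layer, nn.Dropout) for layer in self.head)

    # -- forward / backward ------------------------------------------------

    def _check_batch(self, x: np.ndarray, codes: np.ndarray) -> None:
        size = self.config.image_size
        if x.shape[1:] != (self.config.in_channels, size, size):
            raise ValueError(
                f"expected input of shape (N, {self.config.in_channels}, {size}, {size}),"
                f" got {x.shape}"
            )
        if codes.shape[1] != self.config.structure_code_length:
            raise ValueError(
                f"structure code length {codes.shape[1]} != configured "
                f"{self.config.structure_code_length}"
            )

    def forward_logits(
        self,
        x: np.ndarray,
        codes: np.ndarray,
        train: bool = False,
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Logits for a batch; dropout fires only when ``dropout_rng`` is given."""
        self._check_batch(x, codes)
        out = self.stem_relu.forward(self.stem_bn.forward(self.stem_conv.forward(x), train))
        for block in self.blocks:
            out = block.forward(out, train)
        feats = self.pool.forward(out)
        h = np.concatenate([feats, codes], axis=1)
        self._code_len = codes.shape[1]
        for layer in self.head:
            if isinstance(layer, nn.Dropout):
                h = layer.forward(h, dropout_rng)
            else:
                h = layer.forward(h)
        return h[:, 0]

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits[:, None]
        for layer in reversed(self.head):
            g = layer.backward(g)
        g = g[:, : -self._code_len]  # gradient w.r.t. pooled features only
        g = self.pool.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        self.stem_conv.backward(self.stem_bn.backward(self.stem_relu.backward(g)))

    # -- inference helpers -------------------------------------------------

    def predict_proba(
        self,
        images: np.ndarray,
        masks: np.ndarray,
        codes: np.ndarray,
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> np.ndarray:
        """Revision-required probability for a batch of (image, mask, code)."""
        x = np.stack([images, masks], axis=1).astype(np.float64)
        z = self.forward_logits(x, codes, train=False, dropout_rng=dropout_rng)
        return nn.sigmoid(z)

    def predict_sample(
        self, sample: SliceSample, dropout_rng: Optional[np.random.Generator] = None
    ) -> float:
        p = self.predict_proba(
            sample.image[None], sample.mask[None].astype(np.float64),
            sample.structure_code[None], dropout_rng,
        )
        return float(p[0])


def _batch_arrays(samples: Sequence[SliceSample]):
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples]).astype(np.float64)
    codes = np.stack([s.structure_code for s in samples])
    labels = np.array([s.label for s in samples], dtype=np.float64)
    return images, masks, codes, labels


def _accuracy(model: ContourQualityNet, samples: Sequence[SliceSample],
              batch_size: int = 256) -> float:
    correct = 0
    for i in range(0, len(samples), batch_size):
        chunk = samples[i:i + batch_size]
        images, masks, codes, labels = _batch_arrays(chunk)
        p = model.predict_proba(images, masks, codes)
        correct += int(((p >= 0.5).astype(int) == labels.astype(int)).sum())
    return correct / len(samples)


def train(
    model: ContourQualityNet,
    epoch_builder: Callable[[np.random.Generator], list[SliceSample]],
    val_samples: Sequence[SliceSample],
    config: TrainConfig,
) -> tuple[ContourQualityNet, list[dict]]:
    """Train with BCE + Adam on balanced epochs; keep the best-validation weights.

    ``epoch_builder`` is called once per epoch with an epoch-specific generator
    so revision-required samples are regenerated dynamically.  Returns the
    model (weights reset to the best validation-accuracy checkpoint) and a
    per-epoch log of loss, learning rate and validation accuracy.
    """
    optimizer = nn.Adam(model.parameters(), lr=config.initial_lr)
    log: list[dict] = []
    best_state = model.state()
    best_val = -1.0
    for epoch in range(config.epochs):
        lr = learning_rate_at(config, epoch)
        optimizer.lr = lr
        epoch_rng = np.random.default_rng([config.seed, epoch])
        samples = epoch_builder(epoch_rng)
        dropout_rng = np.random.default_rng([config.seed, epoch, 1])
        losses = []
        for i in range(0, len(samples), config.batch_size):
            chunk = samples[i:i + config.batch_size]
            images, masks, codes, labels = _batch_arrays(chunk)
            x = np.stack([images, masks], axis=1)
            optimizer.zero_grad()
            logits = model.forward_logits(x, codes, train=True, dropout_rng=dropout_rng)
            loss, grad = nn.bce_with_logits(logits, labels)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}, batch {i // config.batch_size}"
                )
            model.backward(grad)
            optimizer.step()
            losses.append(loss)
        val_acc = _accuracy(model, val_samples) if len(val_samples) else float("nan")
        log.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)),
                    "val_accuracy": val_acc})
        if len(val_samples) and val_acc > best_val:
            best_val = val_acc
            best_state = model.state()
    model.load_state(best_state)
    return model, log


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: ContourQualityNet, catalogue: StructureCatalogue,
                    train_config: Optional[TrainConfig] = None) -> None:
    """Self-describing archive: weights + model config + structure catalogue."""
    meta = {
        "model_config": asdict(model.config),
        "structures": list(catalogue.names),
        "train_config": asdict(train_config) if train_config else None,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple[ContourQualityNet, StructureCatalogue]:
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        arrays = [archive[f"arr_{i}"] for i in range(len(archive.files) - 1)]
    cfg = meta["model_config"]
    cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
    model = ContourQualityNet(ModelConfig(**cfg))
    model.load_state(arrays)
    catalogue = StructureCatalogue(names=tuple(meta["structures"]))
    return model, catalogue
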