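"""Labeled slice-level samples and balanced per-structure sampling.

A QA unit is one :class:`SliceSample`: an image slice, one structure's binary
mask, the structure's one-hot code, and a binary label (0 = acceptable,
1 = revision required).  Revision-required samples always carry the
:class:`~contourqa.perturb.PerturbationSpec` that produced them.

Training epochs are balanced per structure: every acceptable sample is paired
with a freshly perturbed counterpart, regenerated each epoch so the model
never sees the same synthetic error twice.  Test sets use the same pairing but
are frozen by a single seed so evaluations are reproducible bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .perturb import PerturbationSpec, sample_perturbation
from .phantom import PhantomPatient

__all__ = [
    "StructureCatalogue",
    "SliceSample",
    "encode_structure",
    "acceptable_pools",
    "build_epoch",
    "build_balanced_set",
    "load_manifest",
    "write_test_manifest",
    "read_test_manifest",
]


@dataclass(frozen=True)
class StructureCatalogue:
    """Ordered structure names; the index of a name is its integer code."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("structure names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def code_of(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown structure {name!r}; catalogue has {self.names}") from None

    def one_hot(self, name: str) -> np.ndarray:
        vec = np.zeros(len(self.names), dtype=np.float64)
        vec[self.code_of(name)] = 1.0
        return vec


def encode_structure(name: str, catalogue: StructureCatalogue) -> np.ndarray:
    """One-hot encode a structure name (length K, single 1 at its code)."""
    return catalogue.one_hot(name)


@dataclass(frozen=True)
class SliceSample:
    image: np.ndarray
    mask: np.ndarray
    structure: str
    structure_code: np.ndarray  # one-hot, length K
    label: int  # 0 = acceptable, 1 = revision required
    patient_id: str
    slice_index: int
    perturbation: Optional[PerturbationSpec] = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if (self.label == 1) != (self.perturbation is not None):
            raise ValueError("label 1 iff a perturbation is recorded")

    @property
    def sample_id(self) -> str:
        suffix = "rev" if self.label == 1 else "ok"
        return f"{self.patient_id}/s{self.slice_index}/{self.structure}/{suffix}"


def acceptable_pools(
    patients: Sequence[PhantomPatient], catalogue: StructureCatalogue
) -> dict[str, list[SliceSample]]:
    """Per-structure lists of acceptable (label 0) samples from phantom patients."""
    pools: dict[str, list[SliceSample]] = {name: [] for name in catalogue.names}
    for patient in patients:
        for k, sl in enumerate(patient.slices):
            for code, mask in sl.masks.items():
                name = catalogue.names[code]
                pools[name].append(
                    SliceSample(
                        image=sl.image,
                        mask=mask,
                        structure=name,
                        structure_code=catalogue.one_hot(name),
                        label=0,
                        patient_id=patient.patient_id,
                        slice_index=k,
                    )
                )
    return pools


def _perturbed_copy(sample: SliceSample, rng: np.random.Generator) -> SliceSample:
    mask, spec = sample_perturbation(sample.mask, rng)
    return replace(sample, mask=mask, label=1, perturbation=spec)


def build_epoch(
    pools: dict[str, list[SliceSample]], rng: np.random.Generator
) -> list[SliceSample]:
    """One balanced, shuffled training epoch.

    For every structure, each acceptable sample appears once together with a
    freshly drawn revision-required counterpart, so class counts are exactly
    balanced per structure.  Perturbations are regenerated on every call.
    """
    epoch: list[SliceSample] = []
    for name in sorted(pools):
        pool = pools[name]
        if not pool:
            raise ValueError(f"structure {name!r} has no acceptable samples")
        epoch.extend(pool)
        epoch.extend(_perturbed_copy(s, rng) for s in pool)
    order = rng.permutation(len(epoch))
    return [epoch[i] for i in order]


def build_balanced_set(
    pools: dict[str, list[SliceSample]], seed: int
) -> list[SliceSample]:
    """Frozen balanced evaluation set: one perturbed twin per acceptable slice.

    Unlike :func:`build_epoch` the result is meant to be generated once (the
    seed freezes every perturbation draw) and reused across evaluations.
    """
    rng = np.random.default_rng(seed)
    out: list[SliceSample] = []
    for name in sorted(pools):
        pool = pools[name]
        if not pool:
            raise ValueError(f"structure {name!r} has no acceptable samples")
        for s in pool:
            out.append(s)
            out.append(_perturbed_copy(s, rng))
    return out


# ---------------------------------------------------------------------------
# manifest I/O (phantom writer dialect)
# ---------------------------------------------------------------------------

def _read_image(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    return arr.astype(np.float64) / 255.0


def _read_mask(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    return (iio.imread(path) > 0).astype(np.uint8)


def load_manifest(
    root, catalogue: Optional[StructureCatalogue] = None
) -> tuple[StructureCatalogue, dict[str, dict[str, list[SliceSample]]]]:
    """Read a phantom ``manifest.csv`` tree back into per-split sample pools.

    Returns the catalogue (inferred from the manifest if not given) and a
    mapping split -> structure -> list of acceptable samples.
    """
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    if catalogue is None:
        names = tuple(dict.fromkeys(manifest["structure"]))
        catalogue = StructureCatalogue(names=names)
    splits: dict[str, dict[str, list[SliceSample]]] = {}
    image_cache: dict[str, np.ndarray] = {}
    for row in manifest.itertuples():
        if row.image_path not in image_cache:
            image_cache[row.image_path] = _read_image(root / row.image_path)
        sample = SliceSample(
            image=image_cache[row.image_path],
            mask=_read_mask(root / row.mask_path),
            structure=row.structure,
            structure_code=catalogue.one_hot(row.structure),
            label=0,
            patient_id=row.patient_id,
            slice_index=int(row.slice_index),
        )
        splits.setdefault(row.split, {}).setdefault(row.structure, []).append(sample)
    return catalogue, splits


def write_test_manifest(path, samples: Sequence[SliceSample]) -> pd.DataFrame:
    """Persist a frozen evaluation set's bookkeeping (not the pixel data).

    One row per sample: id, provenance, label and the JSON-encoded
    perturbation spec for revision-required rows.
    """
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "slice_index": s.slice_index,
                "structure": s.structure,
                "label": s.label,
                "perturbation": json.dumps(s.perturbation.to_dict()) if s.perturbation else "",
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_test_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)


def replay_test_manifest(root, manifest_path) -> tuple[StructureCatalogue, list[SliceSample]]:
    """Rebuild a frozen evaluation set from a phantom tree + test manifest.

    Acceptable pixel data are reloaded from the phantom ``manifest.csv`` under
    ``root``; revision-required rows re-apply their logged perturbation specs,
    which is deterministic, so the rebuilt set matches the original
    bit-for-bit.
    """
    from .perturb import apply_perturbation

    catalogue, splits = load_manifest(root)
    by_key: dict[tuple, SliceSample] = {}
    for pools in splits.values():
        for samples in pools.values():
            for s in samples:
                by_key[(s.patient_id, s.slice_index, s.structure)] = s
    out: list[SliceSample] = []
    for row in read_test_manifest(manifest_path).itertuples():
        base = by_key[(row.patient_id, int(row.slice_index), row.structure)]
        if int(row.label) == 0:
            out.append(base)
        else:
            spec = PerturbationSpec.from_dict(json.loads(row.perturbation))
            out.append(replace(base, mask=apply_perturbation(base.mask, spec),
                               label=1, perturbation=spec))
    return catalogue, out
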