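"""Synthetic phantom cohorts for contour-QA development.

Real MR slices with clinically approved organ contours are not shippable, so
this module fabricates "patients": stacks of 2D grayscale slices containing
bright elliptical blobs on a noisy background, one blob per anatomical
structure class, together with exact binary ground-truth masks.  Three default
structure classes with distinct characteristic sizes (a large bladder-like, a
medium prostate-like and a small urethra-like blob) are provided so that the
size dependence of mask perturbations is exercised.

The mask of a structure is the exact rasterization of its ellipse *before*
blur and noise are applied to the image, i.e. the ground truth is clean by
construction.  Images are normalized to [0, 1] at generation time; that range
is the package-wide intensity contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomConfig",
    "PhantomPatient",
    "PhantomSlice",
    "default_structure_names",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
]


def default_structure_names(n: int) -> tuple[str, ...]:
    """Structure class names, largest first."""
    base = ["bladder_like", "prostate_like", "urethra_like"]
    if n <= len(base):
        return tuple(base[:n])
    return tuple(base + [f"organ_{i}" for i in range(len(base), n)])


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one synthetic cohort.

    ``semi_axis_ranges`` gives inclusive (min, max) pixel ranges for the two
    ellipse semi-axes of each structure class; ``foreground_means`` the mean
    intensity of each blob.  Both are cycled if ``n_structures`` exceeds their
    length.  Structures sit on a ring of radius ``ring_radius`` around the
    image center, jittered per slice by up to ``center_jitter`` pixels.
    """

    image_size: int = 64
    n_structures: int = 3
    slices_per_patient: tuple[int, int] = (2, 4)
    background_mean: float = 0.25
    background_sigma: float = 0.05
    foreground_means: tuple[float, ...] = (0.85, 0.70, 0.55)
    blur_sigma: float = 0.7
    semi_axis_ranges: tuple[tuple[float, float], ...] = ((8, 14), (5, 8), (3, 5))
    ring_radius: float = 10.0
    center_jitter: float = 4.0
    seed: int = 0

    @property
    def structure_names(self) -> tuple[str, ...]:
        return default_structure_names(self.n_structures)

    def semi_axis_range(self, k: int) -> tuple[float, float]:
        return self.semi_axis_ranges[k % len(self.semi_axis_ranges)]

    def foreground_mean(self, k: int) -> float:
        return self.foreground_means[k % len(self.foreground_means)]

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        lo, hi = self.slices_per_patient
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid slices_per_patient range {self.slices_per_patient}")
        half = self.image_size / 2
        for k in range(self.n_structures):
            a_min, a_max = self.semi_axis_range(k)
            if not (0 < a_min <= a_max):
                raise ValueError(f"invalid semi-axis range for structure {k}")
            if a_max >= half:
                raise ValueError(
                    f"structure {k}: max semi-axis {a_max} does not fit in a "
                    f"{self.image_size}px frame"
                )
            reach = self.ring_radius + self.center_jitter + a_max
            if reach > half - 2:
                raise ValueError(
                    f"structure {k}: center excursion + semi-axis ({reach:.1f}px) "
                    f"can leave the frame (limit {half - 2:.1f}px)"
                )
            contrast = abs(self.foreground_mean(k) - self.background_mean)
            if contrast < 2 * self.background_sigma:
                raise ValueError(
                    f"structure {k}: foreground/background contrast {contrast:.3f} "
                    f"below 2 noise sigma ({2 * self.background_sigma:.3f}); "
                    "structures would not be learnable"
                )


@dataclass(frozen=True)
class PhantomSlice:
    image: np.ndarray  # float64 in [0, 1], (H, W)
    masks: dict[int, np.ndarray]  # structure code -> uint8 {0,1}, (H, W)
    # ground-truth ellipse per structure: (cy, cx, ay, ax), for provenance
    ellipses: dict[int, tuple[float, float, float, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class PhantomPatient:
    patient_id: str
    slices: tuple[PhantomSlice, ...] = field(default_factory=tuple)


def _ellipse_mask(size: int, cy: float, cx: float, ay: float, ax: float) -> np.ndarray:
    """Exact rasterization: pixel centers with (dy/ay)^2 + (dx/ax)^2 <= 1."""
    yy, xx = np.mgrid[0:size, 0:size]
    inside = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    return inside.astype(np.uint8)


def generate_patient(
    config: PhantomConfig, patient_id: str, rng: np.random.Generator
) -> PhantomPatient:
    """Render one synthetic patient, deterministically for a given ``rng``.

    Each slice carries one mask per structure class; the mask is the exact
    ellipse indicator before blur/noise.
    """
    config.validate()
    size = config.image_size
    lo, hi = config.slices_per_patient
    n_slices = int(rng.integers(lo, hi + 1))
    center = (size - 1) / 2.0

    slices = []
    for _ in range(n_slices):
        fg = np.zeros((size, size))
        masks: dict[int, np.ndarray] = {}
        ellipses: dict[int, tuple[float, float, float, float]] = {}
        for k in range(config.n_structures):
            angle = 2 * math.pi * k / config.n_structures
            jitter = rng.uniform(-config.center_jitter, config.center_jitter, size=2)
            cy = center + config.ring_radius * math.sin(angle) + jitter[0]
            cx = center + config.ring_radius * math.cos(angle) + jitter[1]
            a_min, a_max = config.semi_axis_range(k)
            ay = rng.uniform(a_min, a_max)
            ax = rng.uniform(a_min, a_max)
            mask = _ellipse_mask(size, cy, cx, ay, ax)
            masks[k] = mask
            ellipses[k] = (cy, cx, ay, ax)
            contrast = config.foreground_mean(k) - config.background_mean
            # overlapping blobs keep the brighter value rather than summing
            fg = np.maximum(fg, contrast * mask)
        image = config.background_mean + fg
        image = gaussian_filter(image, sigma=config.blur_sigma)
        image = image + rng.normal(0.0, config.background_sigma, size=(size, size))
        image = np.clip(image, 0.0, 1.0)
        slices.append(PhantomSlice(image=image, masks=masks, ellipses=ellipses))
    return PhantomPatient(patient_id=patient_id, slices=tuple(slices))


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # one independent stream per global patient index: split membership and
    # content are stable however many patients are requested downstream
    return np.random.default_rng([seed, index])


def generate_cohort(
    config: PhantomConfig, n_train: int, n_val: int, n_test: int
) -> tuple[list[PhantomPatient], list[PhantomPatient], list[PhantomPatient]]:
    """Generate disjoint train/validation/test patient lists.

    Patient ids encode the split (``train_0007``) and are globally unique; the
    same config and seed always reproduce the same cohort.
    """
    config.validate()
    for name, n in (("n_train", n_train), ("n_val", n_val), ("n_test", n_test)):
        if n < 1:
            raise ValueError(f"{name} must be >= 1, got {n}")
    splits: list[list[PhantomPatient]] = []
    index = 0
    for split_name, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        patients = []
        for i in range(n):
            pid = f"{split_name}_{i:04d}"
            patients.append(generate_patient(config, pid, _patient_rng(config.seed, index)))
            index += 1
        splits.append(patients)
    return splits[0], splits[1], splits[2]


def with_seed(config: PhantomConfig, seed: int) -> PhantomConfig:
    return replace(config, seed=seed)


def write_cohort(
    out_dir,
    config: PhantomConfig,
    cohort: dict[str, list[PhantomPatient]],
) -> "pandas.DataFrame":  # noqa: F821 - forward name for doc only
    """Write patients as 16-bit PNGs plus a ``manifest.csv``.

    Layout: ``<out>/<patient_id>/image_<k>.png`` (16-bit grayscale) and
    ``mask_<structure>_<k>.png`` (0/255).  The manifest has one row per
    (slice, structure) with columns split, patient_id, slice_index, structure,
    image_path, mask_path (paths relative to ``out_dir``).
    """
    import imageio.v3 as iio
    import pandas as pd
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = config.structure_names
    rows = []
    for split, patients in cohort.items():
        for patient in patients:
            pdir = out / patient.patient_id
            pdir.mkdir(exist_ok=True)
            for k, sl in enumerate(patient.slices):
                img16 = np.round(sl.image * 65535).astype(np.uint16)
                image_rel = f"{patient.patient_id}/image_{k}.png"
                iio.imwrite(out / image_rel, img16)
                for code, mask in sl.masks.items():
                    mask_rel = f"{patient.patient_id}/mask_{names[code]}_{k}.png"
                    iio.imwrite(out / mask_rel, (mask * 255).astype(np.uint8))
                    rows.append(
                        {
                            "split": split,
                            "patient_id": patient.patient_id,
                            "slice_index": k,
                            "structure": names[code],
                            "image_path": image_rel,
                            "mask_path": mask_rel,
                        }
                    )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
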