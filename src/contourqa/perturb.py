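"""Synthetic segmentation-error operators.

Revision-required masks are manufactured from clean masks with one of four
small, anatomically plausible error families:

* ``dilate`` / ``erode`` — expand or contract the boundary by ~2 px along the
  x-axis, the y-axis, or both (rectangular structuring elements);
* ``shift`` — translate the whole mask by an integer offset within +/-2 px,
  with (0, 0) explicitly excluded;
* ``boundary_noise`` — displace up to 15 contour vertices by integer offsets
  within +/-2 px per axis, then redraw and fill the deformed polygon.

Coordinate convention, used package-wide: arrays are (row, col) = (y, x),
0-based; "x-axis" means image columns.  A perturbation that collapses to the
identity or empties the mask raises :class:`DegeneratePerturbationError`; the
sampler responds by redrawing a fresh family/parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import draw, measure

__all__ = [
    "FAMILIES",
    "DegeneratePerturbationError",
    "PerturbationSpec",
    "dilate_or_erode",
    "shift_mask",
    "boundary_noise",
    "sample_perturbation",
    "apply_perturbation",
]

FAMILIES = ("dilate", "erode", "shift", "boundary_noise")
AXIS_MODES = ("x", "y", "both")

MAX_SHIFT = 2  # px, per axis
MAX_BOUNDARY_POINTS = 15
MAX_OFFSET = 2  # px, per axis, boundary noise
DEFAULT_MAGNITUDE = 2  # px, dilation/erosion


class DegeneratePerturbationError(ValueError):
    """The drawn perturbation produced no usable revision-required mask."""


@dataclass(frozen=True)
class PerturbationSpec:
    """Family plus the sampled parameters that produced a perturbed mask."""

    family: str
    axis_mode: Optional[str] = None  # dilate/erode
    magnitude_px: int = DEFAULT_MAGNITUDE  # dilate/erode
    shift_dx: int = 0  # shift, columns
    shift_dy: int = 0  # shift, rows
    n_points: int = 0  # boundary_noise
    point_indices: Optional[tuple[int, ...]] = None  # boundary_noise vertices
    offsets: Optional[tuple[tuple[int, int], ...]] = None  # per-point (dx, dy)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.family in ("dilate", "erode"):
            if self.axis_mode not in AXIS_MODES:
                raise ValueError(f"axis_mode must be one of {AXIS_MODES}")
            if self.magnitude_px < 1:
                raise ValueError("magnitude_px must be >= 1")
        elif self.family == "shift":
            if (self.shift_dx, self.shift_dy) == (0, 0):
                raise ValueError("shift of (0, 0) is excluded")
            if abs(self.shift_dx) > MAX_SHIFT or abs(self.shift_dy) > MAX_SHIFT:
                raise ValueError(f"shift must lie within +/-{MAX_SHIFT} px")
        elif self.family == "boundary_noise":
            if not (1 <= self.n_points <= MAX_BOUNDARY_POINTS):
                raise ValueError(f"n_points must be in [1, {MAX_BOUNDARY_POINTS}]")
            if self.offsets is None or len(self.offsets) != self.n_points:
                raise ValueError("boundary_noise needs one (dx, dy) offset per point")
            for dx, dy in self.offsets:
                if abs(dx) > MAX_OFFSET or abs(dy) > MAX_OFFSET:
                    raise ValueError(f"offsets must lie within +/-{MAX_OFFSET} px")

    @classmethod
    def from_dict(cls, d: dict) -> "PerturbationSpec":
        kwargs = dict(d)
        if "point_indices" in kwargs and kwargs["point_indices"] is not None:
            kwargs["point_indices"] = tuple(int(i) for i in kwargs["point_indices"])
        if "offsets" in kwargs and kwargs["offsets"] is not None:
            kwargs["offsets"] = tuple((int(a), int(b)) for a, b in kwargs["offsets"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {"family": self.family}
        if self.family in ("dilate", "erode"):
            d.update(axis_mode=self.axis_mode, magnitude_px=self.magnitude_px)
        elif self.family == "shift":
            d.update(shift_dx=self.shift_dx, shift_dy=self.shift_dy)
        else:
            d.update(
                n_points=self.n_points,
                point_indices=list(self.point_indices or ()),
                offsets=[list(o) for o in (self.offsets or ())],
            )
        return d


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    return (mask > 0).astype(np.uint8)


def _structuring_element(axis_mode: str, magnitude: int) -> np.ndarray:
    w = 2 * magnitude + 1
    if axis_mode == "x":
        return np.ones((1, w), dtype=bool)
    if axis_mode == "y":
        return np.ones((w, 1), dtype=bool)
    return np.ones((w, w), dtype=bool)


def dilate_or_erode(mask: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Expand or contract the mask boundary along the selected axes.

    Dilation must strictly grow and erosion strictly shrink the mask; an
    erosion that empties the mask (or either operation that changes nothing,
    e.g. a frame-filling mask) is degenerate.
    """
    if spec.family not in ("dilate", "erode"):
        raise ValueError(f"spec family {spec.family!r} is not dilate/erode")
    m = _as_binary(mask)
    if m.sum() == 0:
        raise DegeneratePerturbationError("empty input mask")
    selem = _structuring_element(spec.axis_mode, spec.magnitude_px)
    if spec.family == "dilate":
        out = ndimage.binary_dilation(m, structure=selem)
    else:
        out = ndimage.binary_erosion(m, structure=selem)
    out = out.astype(np.uint8)
    if out.sum() == 0:
        raise DegeneratePerturbationError("erosion emptied the mask")
    if out.sum() == m.sum():
        raise DegeneratePerturbationError("morphology left the mask unchanged")
    return out


def shift_mask(mask: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Translate the whole mask by (dx, dy); pixels leaving the frame are lost."""
    if spec.family != "shift":
        raise ValueError(f"spec family {spec.family!r} is not shift")
    m = _as_binary(mask)
    out = np.zeros_like(m)
    h, w = m.shape
    dy, dx = spec.shift_dy, spec.shift_dx
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = m[src_y, src_x]
    if out.sum() == 0:
        raise DegeneratePerturbationError("shift pushed the mask out of frame")
    return out


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Longest closed iso-0.5 contour of the mask, as (row, col) vertices.

    The closing duplicate vertex is dropped; vertices are in traversal order.
    """
    m = _as_binary(mask)
    contours = measure.find_contours(m.astype(float), 0.5)
    if not contours:
        raise DegeneratePerturbationError("mask has no traceable boundary")
    contour = max(contours, key=len)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    # fewer than 8 vertices means sub-2x2-pixel support: too small to deform
    if len(contour) < 8:
        raise DegeneratePerturbationError("boundary too short to perturb")
    return contour


def _fill_polygon(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = draw.polygon(vertices[:, 0], vertices[:, 1], shape=shape)
    out = np.zeros(shape, dtype=np.uint8)
    out[rr, cc] = 1
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = measure.label(mask, return_num=True, connectivity=2)
    if n <= 1:
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return (labels == counts.argmax()).astype(np.uint8)


def boundary_noise(mask: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    """Displace selected boundary vertices, then redraw and fill the contour.

    ``spec.point_indices`` selects vertices along the traced boundary (evenly
    spaced if omitted); each moves by its (dx, dy) offset.  If the refilled
    polygon splits into several components the largest is kept, preserving the
    one-structure-one-region reading of a contour.
    """
    if spec.family != "boundary_noise":
        raise ValueError(f"spec family {spec.family!r} is not boundary_noise")
    m = _as_binary(mask)
    if m.sum() == 0:
        raise DegeneratePerturbationError("empty input mask")
    contour = trace_boundary(m)
    n_vertices = len(contour)
    if spec.n_points > n_vertices:
        raise DegeneratePerturbationError(
            f"boundary has {n_vertices} vertices, fewer than n_points={spec.n_points}"
        )
    if spec.point_indices is None:
        indices = np.linspace(0, n_vertices, spec.n_points, endpoint=False).astype(int)
    else:
        indices = np.asarray(spec.point_indices, dtype=int)
        if len(indices) != spec.n_points or (indices >= n_vertices).any() or (indices < 0).any():
            raise ValueError("point_indices must be n_points valid vertex indices")
    perturbed = contour.copy()
    for idx, (dx, dy) in zip(indices, spec.offsets):
        perturbed[idx, 0] += dy  # row
        perturbed[idx, 1] += dx  # col
    out = _fill_polygon(perturbed, m.shape)
    out = _largest_component(out)
    if out.sum() == 0:
        raise DegeneratePerturbationError("refilled polygon is empty")
    return out


def apply_perturbation(mask: np.ndarray, spec: PerturbationSpec) -> np.ndarray:
    if spec.family in ("dilate", "erode"):
        return dilate_or_erode(mask, spec)
    if spec.family == "shift":
        return shift_mask(mask, spec)
    return boundary_noise(mask, spec)


# the 24 admissible shift offsets: [-2, 2]^2 minus (0, 0)
_SHIFT_CHOICES = [
    (dx, dy)
    for dx in range(-MAX_SHIFT, MAX_SHIFT + 1)
    for dy in range(-MAX_SHIFT, MAX_SHIFT + 1)
    if (dx, dy) != (0, 0)
]


def _draw_spec(
    mask: np.ndarray, rng: np.random.Generator, family: str
) -> PerturbationSpec:
    if family in ("dilate", "erode"):
        axis_mode = AXIS_MODES[rng.integers(len(AXIS_MODES))]
        return PerturbationSpec(family=family, axis_mode=axis_mode)
    if family == "shift":
        dx, dy = _SHIFT_CHOICES[rng.integers(len(_SHIFT_CHOICES))]
        return PerturbationSpec(family="shift", shift_dx=dx, shift_dy=dy)
    contour = trace_boundary(mask)
    n_max = min(MAX_BOUNDARY_POINTS, len(contour))
    n_points = int(rng.integers(1, n_max + 1))
    indices = rng.choice(len(contour), size=n_points, replace=False)
    indices = np.sort(indices)
    offsets = tuple(
        (int(rng.integers(-MAX_OFFSET, MAX_OFFSET + 1)), int(rng.integers(-MAX_OFFSET, MAX_OFFSET + 1)))
        for _ in range(n_points)
    )
    return PerturbationSpec(
        family="boundary_noise",
        n_points=n_points,
        point_indices=tuple(int(i) for i in indices),
        offsets=offsets,
    )


def sample_perturbation(
    mask: np.ndarray,
    rng: np.random.Generator,
    family: Optional[str] = None,
    max_retries: int = 25,
) -> tuple[np.ndarray, PerturbationSpec]:
    """Draw a random error family + parameters and apply them to ``mask``.

    The family is uniform over the four (unless forced) and the returned mask
    always differs from the input in at least one pixel; degenerate draws are
    retried with fresh parameters up to ``max_retries`` times.
    """
    m = _as_binary(mask)
    if m.sum() == 0:
        raise ValueError("cannot perturb an empty mask")
    if family is not None and family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    last_err: Optional[Exception] = None
    for _ in range(max_retries):
        fam = family if family is not None else FAMILIES[rng.integers(len(FAMILIES))]
        try:
            spec = _draw_spec(m, rng, fam)
            out = apply_perturbation(m, spec)
        except DegeneratePerturbationError as err:
            last_err = err
            continue
        if np.array_equal(out, m):
            last_err = DegeneratePerturbationError("perturbation equals the input")
            continue
        return out, spec
    raise DegeneratePerturbationError(
        f"no non-degenerate perturbation found in {max_retries} draws: {last_err}"
    )
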