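"""Synthetic error operators: set relations, bounds, determinism."""

import numpy as np
import pytest
from scipy import ndimage

from contourqa.perturb import (
    DegeneratePerturbationError,
    PerturbationSpec,
    boundary_noise,
    dilate_or_erode,
    sample_perturbation,
    shift_mask,
    trace_boundary,
)

from conftest import ellipse_mask, random_blob_masks, square_mask


class TestSpecValidation:
    def test_zero_shift_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            PerturbationSpec(family="shift", shift_dx=0, shift_dy=0)

    def test_shift_bound(self):
        with pytest.raises(ValueError, match="within"):
            PerturbationSpec(family="shift", shift_dx=3, shift_dy=0)

    def test_too_many_boundary_points(self):
        with pytest.raises(ValueError, match="n_points"):
            PerturbationSpec(family="boundary_noise", n_points=16, offsets=((0, 0),) * 16)

    def test_offset_bound(self):
        with pytest.raises(ValueError, match="offsets"):
            PerturbationSpec(family="boundary_noise", n_points=1, offsets=((3, 0),))

    def test_round_trip(self):
        spec = PerturbationSpec(family="boundary_noise", n_points=2,
                                point_indices=(1, 4), offsets=((1, -2), (0, 2)))
        assert PerturbationSpec.from_dict(spec.to_dict()) == spec


class TestDilateErode:
    def test_square_dilated_both_axes_is_larger_square(self):
        mask = square_mask(10, 3, 3, 4)
        out = dilate_or_erode(mask, PerturbationSpec(family="dilate", axis_mode="both"))
        np.testing.assert_array_equal(out, square_mask(10, 1, 1, 8))
        assert mask.sum() == 16 and out.sum() == 64

    def test_erosion_beyond_halfwidth_is_degenerate(self):
        mask = square_mask(10, 3, 3, 4)
        with pytest.raises(DegeneratePerturbationError):
            dilate_or_erode(mask, PerturbationSpec(family="erode", axis_mode="x"))

    def test_x_only_dilation_preserves_row_occupancy(self):
        mask = ellipse_mask(32, 15.0, 16.0, 6, 5)
        out = dilate_or_erode(mask, PerturbationSpec(family="dilate", axis_mode="x"))
        np.testing.assert_array_equal(out.any(axis=1), mask.any(axis=1))

    @pytest.mark.parametrize("axis_mode", ["x", "y", "both"])
    def test_set_relations_on_random_masks(self, axis_mode):
        for mask in random_blob_masks(30, seed=4):
            dil = dilate_or_erode(mask, PerturbationSpec(family="dilate", axis_mode=axis_mode))
            assert ((dil - mask) >= 0).all() and dil.sum() > mask.sum()
            try:
                ero = dilate_or_erode(mask, PerturbationSpec(family="erode", axis_mode=axis_mode))
            except DegeneratePerturbationError:
                continue
            assert ((mask - ero) >= 0).all() and ero.sum() < mask.sum()

    def test_matches_reference_morphology(self):
        # independent oracle: scipy full-kernel dilation on a fixed mask
        mask = ellipse_mask(24, 11.0, 12.0, 5, 4)
        out = dilate_or_erode(mask, PerturbationSpec(family="dilate", axis_mode="both"))
        oracle = ndimage.grey_dilation(mask, size=(5, 5))
        np.testing.assert_array_equal(out, (oracle > 0).astype(np.uint8))


class TestShift:
    def test_pure_translation_preserves_area(self):
        mask = square_mask(10, 3, 3, 4)
        out = shift_mask(mask, PerturbationSpec(family="shift", shift_dx=1, shift_dy=0))
        np.testing.assert_array_equal(out, square_mask(10, 3, 4, 4))

    def test_flush_border_shift_clips_exact_columns(self):
        mask = square_mask(10, 3, 6, 4)  # flush against the right border
        out = shift_mask(mask, PerturbationSpec(family="shift", shift_dx=2, shift_dy=0))
        assert mask.sum() - out.sum() == 2 * 4  # two 4-pixel columns lost

    def test_interior_shift_equals_oracle_translation(self):
        for mask in random_blob_masks(30, seed=5):
            for dx, dy in [(2, 0), (-1, 2), (0, -2), (1, 1)]:
                out = shift_mask(mask, PerturbationSpec(family="shift", shift_dx=dx, shift_dy=dy))
                oracle = np.roll(np.roll(mask, dy, axis=0), dx, axis=1)
                np.testing.assert_array_equal(out, oracle)
                assert out.sum() == mask.sum()

    def test_full_offframe_shift_is_degenerate(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[0, 0] = 1
        with pytest.raises(DegeneratePerturbationError):
            shift_mask(mask, PerturbationSpec(family="shift", shift_dx=-2, shift_dy=-2))


class TestBoundaryNoise:
    def test_identity_offsets_reproduce_the_mask(self):
        mask = ellipse_mask(32, 15.5, 15.5, 8, 6)
        spec = PerturbationSpec(family="boundary_noise", n_points=5,
                                point_indices=(0, 5, 10, 15, 20), offsets=((0, 0),) * 5)
        np.testing.assert_array_equal(boundary_noise(mask, spec), mask)

    def test_single_vertex_displacement_changes_the_mask(self):
        mask = square_mask(16, 5, 5, 6)
        spec = PerturbationSpec(family="boundary_noise", n_points=1,
                                point_indices=(0,), offsets=((2, 2),))
        out = boundary_noise(mask, spec)
        sym_diff = int(np.abs(out.astype(int) - mask.astype(int)).sum())
        assert sym_diff > 0
        # vertices move at most 2 px per axis, so the result stays within the
        # Chebyshev-2 dilation of the (convex) input
        envelope = ndimage.binary_dilation(mask, structure=np.ones((5, 5)))
        assert (out <= envelope).all()

    def test_tiny_mask_is_degenerate(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[4, 4] = 1
        spec = PerturbationSpec(family="boundary_noise", n_points=1,
                                point_indices=(0,), offsets=((1, 1),))
        with pytest.raises(DegeneratePerturbationError):
            boundary_noise(mask, spec)

    def test_n_points_exceeding_boundary_is_degenerate(self):
        mask = square_mask(10, 4, 4, 2)
        n_vertices = len(trace_boundary(mask))
        spec = PerturbationSpec(family="boundary_noise", n_points=min(15, n_vertices + 1),
                                offsets=((1, 1),) * min(15, n_vertices + 1))
        if spec.n_points > n_vertices:
            with pytest.raises(DegeneratePerturbationError):
                boundary_noise(mask, spec)


class TestSampler:
    def test_all_families_observed_and_masks_differ(self, rng):
        mask = ellipse_mask(48, 23.0, 24.0, 10, 8)
        families = set()
        for _ in range(400):
            out, spec = sample_perturbation(mask, rng)
            families.add(spec.family)
            assert out.shape == mask.shape
            assert set(np.unique(out)) <= {0, 1}
            assert np.abs(out.astype(int) - mask.astype(int)).sum() >= 1
        assert families == {"dilate", "erode", "shift", "boundary_noise"}

    def test_zero_shift_never_drawn(self):
        mask = ellipse_mask(20, 9.5, 9.5, 5, 4)
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            _, spec = sample_perturbation(mask, rng, family="shift")
            assert (spec.shift_dx, spec.shift_dy) != (0, 0)

    def test_determinism(self):
        mask = ellipse_mask(32, 15.0, 16.0, 7, 6)
        out1, spec1 = sample_perturbation(mask, np.random.default_rng(77))
        out2, spec2 = sample_perturbation(mask, np.random.default_rng(77))
        assert spec1 == spec2
        np.testing.assert_array_equal(out1, out2)

    def test_pathological_mask_raises_after_retries(self):
        mask = np.zeros((6, 6), dtype=np.uint8)
        mask[3, 3] = 1
        with pytest.raises(DegeneratePerturbationError):
            sample_perturbation(mask, np.random.default_rng(1), family="boundary_noise")

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            sample_perturbation(np.zeros((6, 6), dtype=np.uint8), np.random.default_rng(1))
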