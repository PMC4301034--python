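"""Diffusion, segmentation, nonunion marking, coarsening and cropping."""

import warnings

import numpy as np
import pytest

from minfuse import (CoarseningSpec, DiffusionParams, ImageStack, LabelVolume,
                     PhantomConfig, Slab, Tissue, anisotropic_diffusion,
                     coarsen, coarsened_width, crop_epiphyses, generate_phantom,
                     mark_nonunion, phantom_labels, reduction_percent, segment)


def reference_diffusion(values, iterations, kappa, dt):
    """Independent loop-based explicit Perona-Malik scheme (oracle).

    Zero-flux boundaries are realized by skipping fluxes across the domain
    boundary; conductance g = exp(-(d/kappa)^2) on each axis difference.
    """
    u = np.asarray(values, dtype=np.float64).copy()
    nx, ny, nz = u.shape
    for _ in range(iterations):
        new = u.copy()
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    acc = 0.0
                    for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        ii, jj, kk = i + di, j + dj, k + dk
                        if 0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz:
                            d = u[ii, jj, kk] - u[i, j, k]
                            acc += np.exp(-((d / kappa) ** 2)) * d
                    new[i, j, k] = u[i, j, k] + dt * acc
        u = new
    return u


class TestAnisotropicDiffusion:
    def test_zero_iterations_is_identity(self):
        stack = ImageStack(np.random.default_rng(0).uniform(0, 4095, (6, 6, 6)),
                           (1, 1, 1))
        out = anisotropic_diffusion(stack, DiffusionParams(iterations=0))
        np.testing.assert_array_equal(out.values, stack.values)

    def test_constant_stack_unchanged(self):
        stack = ImageStack(np.full((8, 8, 8), 1234.0), (1, 1, 1))
        out = anisotropic_diffusion(stack, DiffusionParams(iterations=15))
        np.testing.assert_allclose(out.values, stack.values, rtol=1e-12)

    def test_matches_loop_reference_scheme(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 4095, (6, 5, 7))
        params = DiffusionParams(iterations=4, kappa=500.0, dt=0.15)
        expected = reference_diffusion(values, 4, 500.0, 0.15)
        out = anisotropic_diffusion(ImageStack(values, (1, 1, 1)), params)
        np.testing.assert_allclose(out.values, expected, rtol=1e-12)

    def test_large_kappa_smooths_edge_more_than_small_kappa(self):
        # step edge of height 1000: kappa >> step diffuses it, kappa << step
        # treats it as an edge and preserves it
        values = np.zeros((16, 16, 16))
        values[8:] = 1000.0
        stack = ImageStack(values, (1, 1, 1))
        smooth = anisotropic_diffusion(stack, DiffusionParams(iterations=10, kappa=1e5))
        sharp = anisotropic_diffusion(stack, DiffusionParams(iterations=10, kappa=10.0))
        grad = lambda v: np.abs(np.diff(v, axis=0)).max()
        assert grad(smooth.values) < grad(sharp.values)
        np.testing.assert_allclose(sharp.values, values, atol=1.0)

    def test_conserves_global_gray_sum(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 4095, (10, 10, 10))
        out = anisotropic_diffusion(ImageStack(values, (1, 1, 1)),
                                    DiffusionParams(iterations=20, kappa=300.0))
        np.testing.assert_allclose(out.values.sum(), values.sum(), rtol=1e-6)

    def test_unstable_time_step_rejected(self):
        with pytest.raises(ValueError):
            DiffusionParams(dt=0.5)


class TestSegment:
    def test_noiseless_phantom_reproduces_construction_masks(self):
        cfg = PhantomConfig(noise_sd=0.0)
        labels = segment(generate_phantom(cfg))
        np.testing.assert_array_equal(labels.labels, phantom_labels(cfg))

    def test_all_zero_stack_is_background(self):
        labels = segment(ImageStack(np.zeros((4, 4, 4)), (1, 1, 1)))
        assert (labels.labels == Tissue.BACKGROUND).all()

    def test_noisy_phantom_matches_noiseless_labels(self):
        cfg = PhantomConfig(noise_sd=50.0, seed=11)
        truth = phantom_labels(cfg)
        noisy = segment(generate_phantom(cfg))
        agreement = (noisy.labels == truth).mean()
        assert agreement >= 0.99

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            segment(ImageStack(np.zeros((2, 2, 2)), (1, 1, 1)),
                    thresholds=(100, 90, 200, 300))


class TestMarkNonunion:
    def test_gap_slab_marks_exactly_the_gap_soft_voxels(self):
        cfg = PhantomConfig(noise_sd=0.0)
        labels = segment(generate_phantom(cfg))
        zc = cfg.gap_center()
        marked = mark_nonunion(labels, Slab(z=(zc - cfg.gap_halfwidth,
                                               zc + cfg.gap_halfwidth)))
        n_soft_gap = (labels.labels == Tissue.SOFT).sum()
        assert marked.nonunion_mask.sum() == n_soft_gap

    def test_implant_only_region_gives_empty_mask(self):
        cfg = PhantomConfig(noise_sd=0.0)
        labels = segment(generate_phantom(cfg))
        # a sliver inside the plate slab, away from bone
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            marked = mark_nonunion(labels, Slab(x=(40.5, 41.5), z=(20.0, 25.0)))
        assert not marked.nonunion_mask.any()

    def test_zero_thickness_slab_warns_and_is_empty(self):
        cfg = PhantomConfig(noise_sd=0.0)
        labels = segment(generate_phantom(cfg))
        with pytest.warns(UserWarning):
            marked = mark_nonunion(labels, Slab(z=(60.25, 60.3)))
        assert not marked.nonunion_mask.any()


class TestCoarsen:
    @pytest.mark.parametrize("level,width", [
        (1, 512), (2, 256), (3, 170), (4, 128),
        (5, 102), (6, 85), (7, 73), (8, 64),
    ])
    def test_width_ladder_for_512(self, level, width):
        assert coarsened_width(512, level) == width

    def test_levels_beyond_ladder_follow_same_rule(self):
        assert coarsened_width(512, 9) == 56
        assert coarsened_width(512, 10) == 51

    def test_level_one_is_identity(self):
        stack = ImageStack(np.random.default_rng(1).uniform(0, 4095, (9, 9, 4)),
                           (1, 1, 1))
        out = coarsen(stack, CoarseningSpec(level=1))
        np.testing.assert_array_equal(out.values, stack.values)
        assert out.spacing == stack.spacing

    def test_block_mean_preserves_image_mean_when_level_divides(self):
        stack = ImageStack(np.random.default_rng(2).uniform(0, 4095, (8, 8, 3)),
                           (1, 1, 1))
        out = coarsen(stack, CoarseningSpec(level=2))
        np.testing.assert_allclose(out.values.mean(), stack.values.mean(), rtol=1e-12)

    def test_remainder_pixels_dropped_and_spacing_scaled(self):
        stack = ImageStack(np.ones((10, 10, 4)), (0.5, 0.5, 2.0))
        out = coarsen(stack, CoarseningSpec(level=3))
        assert out.values.shape == (3, 3, 4)
        assert out.spacing == (1.5, 1.5, 2.0)

    def test_segment_commutes_with_level_one_coarsening(self):
        cfg = PhantomConfig(noise_sd=30.0, seed=5, grid_dims=(20, 20, 40),
                            outer_radius=6, cortical_thickness=2,
                            plate_thickness=3, plate_width=8,
                            plate_z_extent=(4, 36), screw_radius=1.5,
                            screw_z_positions=(12.0, 28.0), gap_halfwidth=2.0)
        stack = generate_phantom(cfg)
        direct = segment(stack)
        via = segment(coarsen(stack, CoarseningSpec(level=1)))
        np.testing.assert_array_equal(via.labels, direct.labels)

    def test_label_volume_coarsening_rethresholds_means(self):
        labels = LabelVolume(
            labels=np.full((4, 4, 2), Tissue.CORTICAL, dtype=np.int8),
            nonunion_mask=np.zeros((4, 4, 2), bool), spacing=(1, 1, 1))
        out = coarsen(labels, CoarseningSpec(level=2))
        assert out.shape == (2, 2, 2)
        assert (out.labels == Tissue.CORTICAL).all()

    def test_level_larger_than_width_rejected(self):
        stack = ImageStack(np.ones((4, 4, 2)), (1, 1, 1))
        with pytest.raises(ValueError):
            coarsen(stack, CoarseningSpec(level=5))

    def test_level_four_reduction_matches_ninety_three_percent(self):
        assert round(reduction_percent(7_545_550, 505_844)) == 93


class TestCropEpiphyses:
    def test_zero_fractions_identity(self):
        stack = ImageStack(np.random.default_rng(4).uniform(0, 10, (4, 4, 10)),
                           (1, 1, 1))
        out = crop_epiphyses(stack, 0.0, 0.0)
        np.testing.assert_array_equal(out.values, stack.values)

    def test_thirty_percent_of_slices_removed(self):
        stack = ImageStack(np.zeros((4, 4, 120)), (1, 1, 1))
        out = crop_epiphyses(stack, 0.15, 0.15)
        assert out.values.shape[2] == 84

    def test_cell_reduction_equals_removed_slice_fraction(self):
        cfg = PhantomConfig(noise_sd=0.0, grid_dims=(20, 20, 40),
                            outer_radius=6, cortical_thickness=2,
                            plate_thickness=3, plate_width=8,
                            plate_z_extent=(4, 36), screw_radius=1.5,
                            screw_z_positions=(12.0, 28.0), gap_halfwidth=2.0)
        labels = segment(generate_phantom(cfg))
        cropped = crop_epiphyses(labels, 0.25, 0.25)
        n_full = (labels.labels != Tissue.BACKGROUND).sum()
        n_crop = (cropped.labels != Tissue.BACKGROUND).sum()
        kept = (labels.labels[:, :, 10:30] != Tissue.BACKGROUND).sum()
        assert n_crop == kept
        assert n_crop < n_full
        # origin shifts by the removed distal slices
        assert cropped.origin[2] == labels.origin[2] + 10.0

    def test_fractions_summing_to_one_rejected(self):
        stack = ImageStack(np.zeros((2, 2, 10)), (1, 1, 1))
        with pytest.raises(ValueError):
            crop_epiphyses(stack, 0.5, 0.5)
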