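"""Superpixels, Laplacian responses and the six texture features."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from spatnet import (
    ValidationError,
    laplacian_response,
    superpixel_segment,
    texture_features,
)
from spatnet.texture import _K_DIAG_ANTI, _K_DIAG_MAIN, _K_ROW, _K_COL, _K_STANDARD, SuperpixelMap

from _oracles import convolve_brute_force
from conftest import full_mask, make_channel, make_mask


def square_mask(shape, margin=2):
    m = np.zeros(shape, bool)
    m[margin:-margin, margin:-margin] = True
    return make_mask(m)


class TestSuperpixelSegment:
    def test_single_superpixel_covers_mask(self, rng):
        mask = square_mask((20, 20))
        img = make_channel(rng.uniform(0, 10, (20, 20)))
        spmap = superpixel_segment(img, mask, 1, seed=0)
        assert spmap.m == 1
        assert np.array_equal(spmap.label_image > 0, mask.pixels)

    def test_labels_partition_mask(self, small_cell):
        channel = small_cell.channels["A"]
        spmap = superpixel_segment(channel, small_cell.cell_mask, 40, seed=0)
        assert 1 <= spmap.m <= 40
        assert np.array_equal(spmap.label_image > 0, small_cell.cell_mask.pixels)
        _, counts = np.unique(spmap.label_image[spmap.label_image > 0], return_counts=True)
        assert counts.sum() == small_cell.cell_mask.area
        assert (counts > 0).all()

    def test_constant_image_gives_balanced_areas(self):
        mask = square_mask((42, 42), margin=1)
        img = make_channel(np.full((42, 42), 3.0))
        spmap = superpixel_segment(img, mask, 4, seed=0)
        assert spmap.m == 4
        _, counts = np.unique(spmap.label_image[spmap.label_image > 0], return_counts=True)
        target = mask.area / 4
        assert (counts > target / 2).all() and (counts < target * 2).all()

    def test_target_beyond_mask_rejected(self):
        mask = square_mask((8, 8), margin=3)
        with pytest.raises(ValidationError):
            superpixel_segment(make_channel(np.ones((8, 8))), mask, 100, seed=0)


class TestLaplacianResponse:
    @pytest.mark.parametrize("variant", ["standard", "modified", "diagonal"])
    def test_constant_image_zero_response(self, variant):
        out = laplacian_response(make_channel(np.full((9, 9), 4.0)), variant)
        assert np.allclose(out, 0.0, atol=1e-12)

    @pytest.mark.parametrize("variant", ["standard", "modified", "diagonal"])
    def test_linear_ramp_vanishes_in_interior(self, variant):
        rr, cc = np.mgrid[0:12, 0:12]
        ramp = 3.0 * rr + 2.0 * cc
        out = laplacian_response(make_channel(ramp), variant)
        assert np.allclose(out[2:-2, 2:-2], 0.0, atol=1e-10)

    def test_matches_brute_force_convolution(self, rng):
        img = rng.uniform(0, 100, size=(10, 10))
        channel = make_channel(img)
        assert np.allclose(
            laplacian_response(channel, "standard"),
            convolve_brute_force(img, _K_STANDARD), atol=1e-9)
        assert np.allclose(
            laplacian_response(channel, "modified"),
            np.abs(convolve_brute_force(img, _K_ROW))
            + np.abs(convolve_brute_force(img, _K_COL)), atol=1e-9)
        assert np.allclose(
            laplacian_response(channel, "diagonal"),
            np.abs(convolve_brute_force(img, _K_ROW))
            + np.abs(convolve_brute_force(img, _K_COL))
            + np.abs(convolve_brute_force(img, _K_DIAG_MAIN))
            + np.abs(convolve_brute_force(img, _K_DIAG_ANTI)), atol=1e-9)

    def test_checkerboard_modified_response_is_constant_interior(self):
        board = (np.indices((10, 10)).sum(axis=0) % 2).astype(float)
        out = laplacian_response(make_channel(board), "modified")
        # each 1D (-1, 2, -1) kernel on a period-1 0/1 checkerboard gives |±2|
        assert np.allclose(out[1:-1, 1:-1], 4.0)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValidationError):
            laplacian_response(make_channel(np.ones((2, 5))), "standard")


class TestTextureFeatures:
    def test_constant_image_features(self):
        mask = square_mask((12, 12), margin=1)
        img = make_channel(np.full((12, 12), 6.0))
        spmap = superpixel_segment(img, mask, 3, seed=0)
        table = texture_features(img, spmap).features
        assert np.allclose(table["pixel_intensity"], 6.0)
        for col in ("energy_laplacian", "modified_laplacian", "diagonal_laplacian",
                    "variance_laplacian", "gray_level_variance"):
            assert np.allclose(table[col], 0.0, atol=1e-12)

    def test_single_superpixel_variances_match_mask_variance(self, rng):
        img_vals = rng.uniform(0, 50, size=(16, 16))
        mask = square_mask((16, 16))
        img = make_channel(img_vals)
        spmap = superpixel_segment(img, mask, 1, seed=0)
        table = texture_features(img, spmap).features
        assert table["gray_level_variance"].iloc[0] == pytest.approx(
            img_vals[mask.pixels].var())
        lap = laplacian_response(img, "standard")
        assert table["variance_laplacian"].iloc[0] == pytest.approx(
            lap[mask.pixels].var())

    def test_two_region_intensity_and_normalization(self):
        img_vals = np.zeros((10, 10))
        img_vals[:, 5:] = 10.0
        labels = np.zeros((10, 10), np.int32)
        labels[:, :5] = 1
        labels[:, 5:] = 2
        spmap = SuperpixelMap(labels, target_n=2)
        table = texture_features(make_channel(img_vals), spmap)
        assert np.allclose(table.features["pixel_intensity"], [0.0, 10.0])
        assert np.allclose(table.normalized["pixel_intensity"], [0.0, 1.0])

    def test_relabeling_invariance(self, small_cell):
        channel = small_cell.channels["A"]
        spmap = superpixel_segment(channel, small_cell.cell_mask, 20, seed=0)
        table = texture_features(channel, spmap).features
        relabeled = spmap.label_image.copy()
        m = spmap.m
        perm = np.concatenate([[0], np.roll(np.arange(1, m + 1), 3)])
        swapped = texture_features(channel, SuperpixelMap(perm[relabeled], m)).features
        merged = np.sort(table.to_numpy(), axis=0)
        merged_swapped = np.sort(swapped.to_numpy(), axis=0)
        assert np.allclose(merged, merged_swapped)

    def test_constant_shift_moves_only_pixel_intensity(self, small_cell):
        channel = small_cell.channels["A"]
        spmap = superpixel_segment(channel, small_cell.cell_mask, 15, seed=0)
        base = texture_features(channel, spmap).features
        shifted = texture_features(channel.with_pixels(channel.pixels + 37.0), spmap).features
        assert np.allclose(shifted["pixel_intensity"], base["pixel_intensity"] + 37.0)
        for col in ("energy_laplacian", "modified_laplacian", "diagonal_laplacian",
                    "variance_laplacian", "gray_level_variance"):
            assert np.allclose(shifted[col], base[col], atol=1e-8)

    def test_area_weighted_gray_level_variance_identity(self, small_cell):
        """Law of total mean: superpixel-weighted variance == mask variance."""
        channel = small_cell.channels["B"]
        spmap = superpixel_segment(channel, small_cell.cell_mask, 30, seed=0)
        table = texture_features(channel, spmap).features
        labels = spmap.label_image[spmap.label_image > 0]
        _, counts = np.unique(labels, return_counts=True)
        weighted = (table["gray_level_variance"].to_numpy() * counts).sum() / counts.sum()
        mask_var = channel.pixels[small_cell.cell_mask.pixels].var()
        assert weighted == pytest.approx(mask_var, abs=1e-10 * max(1.0, mask_var))

    def test_blur_reduces_modified_laplacian_focus(self):
        rng0 = np.random.default_rng(0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img_vals = rng.uniform(0, 100, size=(32, 32))
            mask = square_mask((32, 32))
            spmap = superpixel_segment(make_channel(img_vals), mask, 5, seed=0)
            sharp = texture_features(make_channel(img_vals), spmap).features
            blurred_vals = gaussian_filter(img_vals, sigma=2)
            blurred = texture_features(make_channel(blurred_vals), spmap).features
            assert blurred["modified_laplacian"].mean() < sharp["modified_laplacian"].mean()
        del rng0
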