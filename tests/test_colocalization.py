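"""Colocalization metrics: Pearson, pixel overlap, scatter sampling, areas."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatnet import (
    DegenerateInputError,
    ValidationError,
    generate_cell,
    marker_area_intensity,
    otsu_threshold,
    pearson_pair,
    pixel_overlap,
    sample_intensity_pairs,
)

from _oracles import pearson_two_pass
from conftest import full_mask, make_channel, make_mask, two_marker_spec


class TestPearsonPair:
    def test_perfect_linear_relation(self, rng):
        a = rng.uniform(0, 10, size=(8, 8))
        assert pearson_pair(
            make_channel(a), make_channel(2 * a + 3), full_mask((8, 8))
        ) == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelation(self, rng):
        a = rng.uniform(1, 10, size=(8, 8))
        b = a.max() - a  # negated then shifted into the non-negative range
        assert pearson_pair(
            make_channel(a), make_channel(b), full_mask((8, 8))
        ) == pytest.approx(-1.0, abs=1e-12)

    def test_hand_computed_four_pairs(self):
        a = make_channel(np.array([[1.0, 2.0], [3.0, 4.0]]))
        b = make_channel(np.array([[2.0, 1.0], [4.0, 3.0]]))
        assert pearson_pair(a, b, full_mask((2, 2))) == pytest.approx(0.6, abs=1e-12)

    def test_constant_channel_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_pair(
                make_channel(np.ones((4, 4))),
                make_channel(np.arange(16.0).reshape(4, 4)),
                full_mask((4, 4)),
            )

    def test_agrees_with_two_pass_oracle(self, rng):
        for _ in range(50):
            a = rng.uniform(0, 100, size=(6, 6))
            b = rng.uniform(0, 100, size=(6, 6))
            r = pearson_pair(make_channel(a), make_channel(b), full_mask((6, 6)))
            assert r == pytest.approx(pearson_two_pass(a.ravel(), b.ravel()), abs=1e-12)

    def test_symmetry_and_affine_invariance(self, rng):
        a = rng.uniform(0, 10, size=(7, 7))
        b = rng.uniform(0, 10, size=(7, 7))
        mask = full_mask((7, 7))
        r = pearson_pair(make_channel(a), make_channel(b), mask)
        assert pearson_pair(make_channel(b), make_channel(a), mask) == pytest.approx(r)
        assert pearson_pair(
            make_channel(5 * a + 2), make_channel(b), mask
        ) == pytest.approx(r, abs=1e-10)


class TestPixelOverlap:
    def test_identical_masks_saturate_at_half(self):
        m = np.zeros((5, 5), bool)
        m.flat[:10] = True
        assert pixel_overlap(make_mask(m), make_mask(m)) == 0.5

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0], b[2] = True, True
        assert pixel_overlap(make_mask(a), make_mask(b)) == 0.0

    def test_hand_counted_example(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a.flat[:6] = True  # |A| = 6
        b.flat[4:8] = True  # |B| = 4, intersection = pixels 4, 5
        assert pixel_overlap(make_mask(a), make_mask(b)) == pytest.approx(0.2)
        assert pixel_overlap(make_mask(a), make_mask(b), "union") == pytest.approx(2 / 8)

    def test_both_empty_is_degenerate(self):
        empty = make_mask(np.zeros((3, 3), bool))
        with pytest.raises(DegenerateInputError):
            pixel_overlap(empty, empty)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
    def test_bounds_and_symmetry_property(self, bits_a, bits_b):
        a = np.array([(bits_a >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        b = np.array([(bits_b >> i) & 1 for i in range(16)], bool).reshape(4, 4)
        if not (a.any() or b.any()):
            return
        v = pixel_overlap(make_mask(a), make_mask(b))
        assert 0.0 <= v <= 0.5
        assert v <= min(a.sum(), b.sum()) / (a.sum() + b.sum())
        assert v == pixel_overlap(make_mask(b), make_mask(a))
        assert (v == 0.5) == (np.array_equal(a, b) and a.any())


class TestScatterSample:
    def test_sample_capped_at_population(self, rng):
        mask = np.zeros((20, 20), bool)
        mask.flat[:100] = True
        a = make_channel(rng.uniform(0, 10, (20, 20)))
        b = make_channel(rng.uniform(0, 10, (20, 20)))
        sample = sample_intensity_pairs(a, b, make_mask(mask), 50_000, seed=1)
        assert len(sample) == 100
        assert sample.values.min() >= 0 and sample.values.max() <= 1

    def test_same_seed_reproduces_sample(self, rng):
        a = make_channel(rng.uniform(0, 10, (30, 30)))
        b = make_channel(rng.uniform(0, 10, (30, 30)))
        s1 = sample_intensity_pairs(a, b, full_mask((30, 30)), 200, seed=5)
        s2 = sample_intensity_pairs(a, b, full_mask((30, 30)), 200, seed=5)
        assert np.array_equal(s1.values, s2.values)
        assert np.array_equal(s1.density, s2.density)

    def test_invalid_n_rejected(self, rng):
        a = make_channel(np.ones((4, 4)))
        with pytest.raises(ValidationError):
            sample_intensity_pairs(a, a, full_mask((4, 4)), 0, seed=0)

    def test_density_peaks_inside_clusters(self):
        """KDE weights inside two tight clusters beat uniform background probes."""
        rng = np.random.default_rng(7)
        n = 500
        cluster = np.vstack([
            rng.normal(0.25, 0.02, size=(n, 2)),
            rng.normal(0.75, 0.02, size=(n, 2)),
        ]).clip(0, 1)
        img_a = make_channel(cluster[:, 0].reshape(40, 25) * 100)
        img_b = make_channel(cluster[:, 1].reshape(40, 25) * 100)
        sample = sample_intensity_pairs(img_a, img_b, full_mask((40, 25)), 10_000, seed=3)
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(sample.values.T)
        probes = np.random.default_rng(11).uniform(0, 1, size=(50, 2))
        assert sample.density.mean() > kde(probes.T).mean()


class TestMarkerAreaIntensity:
    def test_solid_square_unchanged(self):
        fg = np.zeros((20, 20), bool)
        fg[5:15, 5:15] = True
        row = marker_area_intensity(
            make_channel(np.ones((20, 20)), "m", pixel_size=0.5),
            make_mask(fg), full_mask((20, 20)), cell_id="c",
        )
        assert row.area_px == 100
        assert row.area_um2 == pytest.approx(100 * 0.25)

    def test_isolated_pixels_removed_by_opening(self):
        fg = np.zeros((15, 15), bool)
        fg[2, 2] = fg[7, 9] = fg[12, 4] = True
        row = marker_area_intensity(
            make_channel(np.ones((15, 15))), make_mask(fg), full_mask((15, 15)))
        assert row.area_px == 0

    def test_mean_intensity_over_cell_mask(self):
        mask = np.zeros((10, 10), bool)
        mask.flat[:20] = True
        row = marker_area_intensity(
            make_channel(np.full((10, 10), 5.0)),
            make_mask(np.zeros((10, 10), bool)), make_mask(mask))
        assert row.mean_intensity == 5.0

    def test_empty_cell_mask_rejected(self):
        with pytest.raises(ValidationError):
            marker_area_intensity(
                make_channel(np.ones((5, 5))),
                make_mask(np.ones((5, 5), bool)),
                make_mask(np.zeros((5, 5), bool)))


def test_overlap_targets_drive_measured_overlap_monotonically():
    """Generator overlap fractions 0 / 0.5 / 1 order the Otsu pixel overlap."""
    for seed in range(3):
        values = []
        for frac in (0.0, 0.5, 1.0):
            cell = generate_cell(two_marker_spec(seed=seed, overlap=frac))
            _, fa = otsu_threshold(cell.channels["A"], cell.cell_mask)
            _, fb = otsu_threshold(cell.channels["B"], cell.cell_mask)
            values.append(pixel_overlap(fa, fb))
        assert values[0] < values[1] < values[2]
        assert values[2] >= 0.45
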