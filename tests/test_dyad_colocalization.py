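"""Manders coefficients, orientation territories, densities, and distances."""

import warnings

import numpy as np
import pytest
from scipy import ndimage

from dyadscape.dyad_colocalization import (
    ChannelPair,
    DEFAULT_KERNEL_SIZES,
    DegenerateImageError,
    dyadic_density,
    manders_from_thresholds,
    manders_mcc,
    nearest_ltcc_distances,
    orientation_masks,
    orientation_mcc,
    preprocess_pair,
    protein_density,
)
from dyadscape.image_core import BinaryMask, Image2D
from dyadscape.synthetic_data import DyadSpec, generate_dyad_pair
from dyadscape.tubule_morphometry import LONGITUDINAL, TRANSVERSE


def _pair(ryr, ltcc, roi=None, ps=0.04):
    ryr = np.asarray(ryr, float)
    if roi is None:
        roi = np.ones(ryr.shape, bool)
    return ChannelPair(Image2D(ryr, ps), Image2D(np.asarray(ltcc, float), ps),
                       BinaryMask(roi, ps))


def brute_force_manders(ryr, ltcc, t_ryr, t_ltcc):
    """Independent oracle: explicit per-pixel loops and running sums."""
    num1 = den1 = num2 = den2 = 0.0
    for i in range(ryr.shape[0]):
        for j in range(ryr.shape[1]):
            r, l = ryr[i, j], ltcc[i, j]
            if l > t_ltcc:
                den1 += l
                if r > t_ryr:
                    num1 += l
            if r > t_ryr:
                den2 += r
                if l > t_ltcc:
                    num2 += r
    return num1 / den1, num2 / den2


class TestManders:
    def test_identical_channels_fully_overlap(self, rng):
        arr = rng.uniform(0, 100, (64, 64)) + 1
        arr[20:40, 20:40] += 300
        pair = _pair(arr, arr)
        res = manders_mcc(pair)
        assert res.m1 == pytest.approx(1.0)
        assert res.m2 == pytest.approx(1.0)

    def test_disjoint_supports_zero_overlap(self):
        a = np.zeros((64, 64))
        b = np.zeros((64, 64))
        a[10:20, 10:20] = 200
        b[40:50, 40:50] = 200
        a += np.linspace(0, 1, 64)[None, :]  # avoid constant-channel failure
        b += np.linspace(0, 1, 64)[:, None]
        res = manders_mcc(_pair(a, b))
        assert res.m1 == pytest.approx(0.0, abs=1e-9)
        assert res.m2 == pytest.approx(0.0, abs=1e-9)

    def test_fixed_8x8_pair_matches_brute_force(self, rng):
        ryr = rng.uniform(0, 255, (8, 8))
        ltcc = rng.uniform(0, 255, (8, 8))
        for t_ryr, t_ltcc in [(50.0, 80.0), (120.0, 30.0), (10.0, 10.0)]:
            m1, m2 = manders_from_thresholds(ryr, ltcc, t_ryr, t_ltcc)
            o1, o2 = brute_force_manders(ryr, ltcc, t_ryr, t_ltcc)
            assert m1 == pytest.approx(o1, abs=1e-12)
            assert m2 == pytest.approx(o2, abs=1e-12)

    def test_scale_invariance(self, rng):
        pair, _ = generate_dyad_pair(DyadSpec(seed=2))
        res0 = manders_mcc(preprocess_pair(pair))
        scaled = ChannelPair(
            pair.ryr.with_pixels(pair.ryr.pixels * 3.0),
            pair.ltcc.with_pixels(pair.ltcc.pixels * 0.5),
            pair.cell_roi,
        )
        res1 = manders_mcc(preprocess_pair(scaled))
        assert res1.m1 == pytest.approx(res0.m1, abs=0.02)
        assert res1.m2 == pytest.approx(res0.m2, abs=0.02)

    def test_all_zero_channel_fails(self):
        a = np.zeros((64, 64))
        with pytest.raises(DegenerateImageError):
            manders_mcc(_pair(a, a))


class TestPreprocess:
    def test_extracellular_cleared_and_constant_zeroed(self):
        roi = np.zeros((64, 64), bool)
        roi[10:50, 10:50] = True
        pair = _pair(np.full((64, 64), 80.0), np.full((64, 64), 40.0), roi)
        out = preprocess_pair(pair)
        assert np.all(out.ryr.pixels[~roi] == 0)
        assert np.all(out.ltcc.pixels[~roi] == 0)
        # flat channels have no structure above the rolling-ball background
        assert np.all(out.ryr.pixels == 0)

    def test_idempotent(self):
        pair, _ = generate_dyad_pair(DyadSpec(seed=1))
        once = preprocess_pair(pair)
        twice = preprocess_pair(once)
        np.testing.assert_allclose(twice.ryr.pixels, once.ryr.pixels, atol=1e-6)

    def test_misaligned_shapes_rejected(self):
        with pytest.raises(ValueError):
            ChannelPair(Image2D(np.ones((32, 32)), 0.04),
                        Image2D(np.ones((32, 48)), 0.04),
                        BinaryMask(np.ones((32, 32), bool), 0.04))


class TestOrientationMasks:
    def test_vertical_stripes_feed_transverse_mask(self):
        arr = np.full((100, 100), 5.0)
        for c in range(10, 100, 20):
            arr[10:90, c:c + 2] = 200.0
        masks = orientation_masks(Image2D(arr, 0.04))
        assert masks.longitudinal_mask.pixels.sum() == 0
        stripes = arr > 100
        covered = (masks.transverse_mask.pixels & stripes).sum() / stripes.sum()
        assert covered > 0.95

    def test_transpose_swaps_masks(self):
        pair, _ = generate_dyad_pair(DyadSpec(seed=3))
        pp = preprocess_pair(pair)
        m = orientation_masks(pp.ryr, pp.cell_roi.pixels)
        mt = orientation_masks(
            pp.ryr.with_pixels(pp.ryr.pixels.T),
            pp.cell_roi.pixels.T)
        # transposing swaps transverse <-> longitudinal territories
        iou_t = (mt.transverse_mask.pixels & m.longitudinal_mask.pixels.T).sum() \
            / max((mt.transverse_mask.pixels | m.longitudinal_mask.pixels.T).sum(), 1)
        assert iou_t > 0.8

    def test_covers_true_zlines(self):
        pair, truth = generate_dyad_pair(DyadSpec(seed=4))
        pp = preprocess_pair(pair)
        masks = orientation_masks(pp.ryr, pp.cell_roi.pixels)
        z = truth.transverse_skeleton
        assert (masks.transverse_mask.pixels & z).sum() / z.sum() > 0.9

    def test_masks_are_disjoint(self):
        pair, _ = generate_dyad_pair(DyadSpec(seed=5))
        pp = preprocess_pair(pair)
        masks = orientation_masks(pp.ryr, pp.cell_roi.pixels)
        assert not np.any(masks.transverse_mask.pixels
                          & masks.longitudinal_mask.pixels)


class TestOrientationMCC:
    def test_full_roi_mask_reduces_to_whole_cell(self):
        pair, _ = generate_dyad_pair(DyadSpec(seed=1))
        pp = preprocess_pair(pair)
        whole = manders_mcc(pp)
        from dyadscape.dyad_colocalization import OrientationMasks
        full = BinaryMask(pp.cell_roi.pixels, pp.pixel_size_um)
        empty = BinaryMask(np.zeros_like(pp.cell_roi.pixels), pp.pixel_size_um)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per = orientation_mcc(pp, OrientationMasks(full, empty))
        assert per[TRANSVERSE].m1 == pytest.approx(whole.m1, abs=1e-9)
        assert per[LONGITUDINAL] is None


class TestDensities:
    def test_blank_and_full_channels(self):
        roi = np.ones((64, 64), bool)
        blank = Image2D(np.zeros((64, 64)), 0.04)
        assert protein_density(blank, roi) == 0.0
        full = Image2D(np.full((64, 64), 100.0), 0.04)
        assert protein_density(full, roi, threshold=50.0) == 100.0

    def test_nucleus_exclusion(self):
        roi = np.ones((64, 64), bool)
        nucleus = np.zeros((64, 64), bool)
        nucleus[:32] = True
        arr = np.zeros((64, 64))
        arr[:32] = 100.0  # all signal inside the nucleus
        d = protein_density(Image2D(arr, 0.04), roi, nucleus, threshold=50.0)
        assert d == 0.0

    def test_dyadic_density_is_exact_product(self):
        assert dyadic_density(10.0, 0.0) == 0.0
        assert dyadic_density(10.0, 1.0) == 10.0
        assert dyadic_density(12.0, 0.75) == pytest.approx(9.0)
        with pytest.raises(ValueError):
            dyadic_density(10.0, 1.5)


class TestNearestDistances:
    def test_contained_support_all_zero(self):
        ryr = np.zeros((32, 32), bool)
        ryr[10:12, 10:12] = True
        hist = nearest_ltcc_distances(ryr, ryr.copy(), 0.1)
        assert np.all(hist.distances_um == 0)
        assert hist.orphaned_fraction == 0.0

    def test_pythagoras(self):
        ltcc = np.zeros((32, 32), bool)
        ltcc[0, 0] = True
        ryr = np.zeros((32, 32), bool)
        ryr[3, 4] = True
        hist = nearest_ltcc_distances(ryr, ltcc, 0.1)
        assert hist.distances_um[0] == pytest.approx(0.5, abs=1e-9)

    def test_matches_brute_force_on_sparse_masks(self, rng):
        shape = (48, 48)
        ryr = np.zeros(shape, bool)
        ltcc = np.zeros(shape, bool)
        ryr[tuple(rng.integers(0, 48, (2, 150)))] = True
        ltcc[tuple(rng.integers(0, 48, (2, 120)))] = True
        hist = nearest_ltcc_distances(ryr, ltcc, 0.2)
        rpts = np.argwhere(ryr)
        lpts = np.argwhere(ltcc)
        oracle = np.sqrt(
            (((rpts[:, None, :] - lpts[None, :, :]) ** 2).sum(-1)).min(1)) * 0.2
        np.testing.assert_allclose(np.sort(hist.distances_um),
                                   np.sort(oracle), atol=1e-9)

    def test_empty_ltcc_flagged_infinite(self):
        ryr = np.zeros((32, 32), bool)
        ryr[5, 5] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hist = nearest_ltcc_distances(ryr, np.zeros((32, 32), bool), 0.1)
        assert hist.all_infinite
        assert hist.orphaned_fraction == 1.0

    def test_counts_sum_to_ryr_pixels(self, rng):
        ryr = rng.random((40, 40)) < 0.1
        ltcc = rng.random((40, 40)) < 0.1
        if not ryr.any() or not ltcc.any():
            pytest.skip("degenerate draw")
        hist = nearest_ltcc_distances(ryr, ltcc, 0.1)
        assert hist.counts.sum() == ryr.sum()

    def test_displacement_right_shifts_distances(self):
        medians = []
        for gaps in (0, 5):
            vals = []
            for seed in range(3):
                pair, truth = generate_dyad_pair(DyadSpec(seed=seed, orphan_gap_count=gaps))
                pp = preprocess_pair(pair)
                mcc = manders_mcc(pp)
                hist = nearest_ltcc_distances(pp.ryr.pixels > mcc.t_ryr,
                                              pp.ltcc.pixels > mcc.t_ltcc,
                                              pp.pixel_size_um)
                vals.append(np.median(hist.distances_um))
            medians.append(np.median(vals))
        assert medians[1] > medians[0]
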