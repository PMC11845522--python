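"""Median volumes and the ROI-masked colocalization battery."""

import numpy as np
import pytest
from scipy import stats

from labnorm import (
    BinaryMask,
    Volume,
    coloc_regression,
    colocalize,
    costes_threshold,
    manders_split,
    median_volume,
    voxel_correlation,
)
from labnorm.group_eval import _orthogonal_fit
from tests.conftest import full_roi


def vol_of(values, shape=None):
    arr = np.asarray(values, dtype=float)
    if shape is not None:
        arr = arr.reshape(shape)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1, 1)
    return Volume(arr, (1, 1, 1))


class TestMedianVolume:
    def test_single_element(self, small_volume):
        np.testing.assert_array_equal(median_volume([small_volume]).voxels, small_volume.voxels)

    def test_odd_count_constants(self):
        vols = [vol_of(np.full(4, c)) for c in (1, 2, 9)]
        np.testing.assert_array_equal(median_volume(vols).voxels, np.full((4, 1, 1), 2.0))

    def test_even_count_uses_central_pair_mean(self):
        vols = [vol_of(np.full(4, c)) for c in (1, 2, 3, 10)]
        np.testing.assert_array_equal(median_volume(vols).voxels, np.full((4, 1, 1), 2.5))

    def test_matches_sort_oracle_and_permutation_invariance(self, rng):
        stacks = [Volume(rng.normal(size=(6, 5, 4)), (1, 1, 1)) for _ in range(7)]
        med = median_volume(stacks)
        data = np.stack([v.voxels for v in stacks])
        expected = np.sort(data, axis=0)[3]  # middle order statistic, n=7
        np.testing.assert_array_equal(med.voxels, expected)
        perm = [stacks[i] for i in rng.permutation(7)]
        np.testing.assert_array_equal(median_volume(perm).voxels, med.voxels)

    def test_mismatched_grids_rejected(self, small_volume):
        other = Volume(np.zeros(small_volume.shape), small_volume.spacing, origin=(9, 9, 9))
        with pytest.raises(ValueError, match="grid"):
            median_volume([small_volume, other])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            median_volume([])


class TestCostes:
    def test_matches_bruteforce_sweep_oracle(self, rng):
        shape = (20, 20, 20)
        base = rng.integers(0, 200, shape).astype(float)
        ch1 = vol_of(np.round(base + rng.normal(0, 20, shape)).clip(0), shape)
        ch2 = vol_of(np.round(0.8 * base + rng.normal(0, 20, shape) + 10).clip(0), shape)
        roi = full_roi(ch1)
        res = costes_threshold(ch1, ch2, roi)
        x, y = ch1.voxels.ravel(), ch2.voxels.ravel()
        a, b = _orthogonal_fit(x, y)
        expected = x.min()
        for T in np.unique(x)[::-1]:
            sel = (x < T) & (y < a * T + b)
            if sel.sum() < 2:
                continue
            xs, ys = x[sel], y[sel]
            if xs.std() == 0 or ys.std() == 0:
                continue
            if np.corrcoef(xs, ys)[0, 1] <= 0:
                expected = T
                break
        assert res.threshold_ch1 == expected
        assert res.threshold_ch2 == pytest.approx(a * expected + b)

    def test_identical_channels_descend_to_minimum(self, rng):
        ch1 = vol_of(rng.integers(1, 50, (6, 6, 6)).astype(float), (6, 6, 6))
        res = costes_threshold(ch1, ch1, full_roi(ch1))
        assert res.threshold_ch1 == ch1.voxels.min()
        assert not res.no_positive_colocalization

    def test_anticorrelated_channels_flagged(self, rng):
        ch1 = vol_of(rng.integers(0, 50, (6, 6, 6)).astype(float), (6, 6, 6))
        ch2 = vol_of(60.0 - ch1.voxels, (6, 6, 6))
        res = costes_threshold(ch1, ch2, full_roi(ch1))
        assert res.no_positive_colocalization
        assert res.threshold_ch1 == ch1.voxels.max()
        assert res.threshold_ch2 == ch2.voxels.max()

    def test_constant_channel_rejected(self, rng):
        ch1 = vol_of(rng.random((4, 4, 4)), (4, 4, 4))
        ch2 = vol_of(np.full((4, 4, 4), 2.0), (4, 4, 4))
        with pytest.raises(ValueError, match="constant"):
            costes_threshold(ch1, ch2, full_roi(ch1))


class TestManders:
    def test_complete_colocalization(self, rng):
        ch = vol_of(rng.uniform(10, 20, (4, 4, 4)), (4, 4, 4))
        tm1, tm2 = manders_split(ch, ch, 5.0, 5.0, full_roi(ch))
        assert tm1 == 1.0 and tm2 == 1.0

    def test_disjoint_supports(self):
        a = np.zeros((4, 1, 1))
        b = np.zeros((4, 1, 1))
        a[:2] = 7.0
        b[2:] = 5.0
        ch1, ch2 = vol_of(a.ravel()), vol_of(b.ravel())
        tm1, tm2 = manders_split(ch1, ch2, 0.0, 0.0, full_roi(ch1))
        assert tm1 == 0.0 and tm2 == 0.0

    def test_four_voxel_hand_computation(self):
        ch1 = vol_of([10.0, 10.0, 0.0, 0.0])
        ch2 = vol_of([10.0, 0.0, 10.0, 0.0])
        tm1, tm2 = manders_split(ch1, ch2, 5.0, 5.0, full_roi(ch1))
        assert tm1 == 0.5 and tm2 == 0.5

    def test_negative_intensities_clipped(self):
        ch1 = vol_of([-5.0, 10.0, 10.0, 0.0])
        ch2 = vol_of([10.0, 10.0, 0.0, 0.0])
        tm1, _ = manders_split(ch1, ch2, 5.0, 5.0, full_roi(ch1))
        assert tm1 == 0.5  # (0 + 10) above-threshold ch2 voxels / 20 total

    def test_all_zero_channel_rejected(self):
        ch1 = vol_of([0.0, 0.0, 0.0, 0.0])
        ch2 = vol_of([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="all-zero"):
            manders_split(ch1, ch2, 0.0, 0.0, full_roi(ch1))


class TestCorrelationAndRegression:
    def test_perfect_monotone_agreement(self, rng):
        ch = vol_of(rng.random(60))
        r, rho = voxel_correlation(ch, ch, full_roi(ch))
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0)

    def test_perfect_inversion(self, rng):
        ch1 = vol_of(rng.random(60))
        ch2 = vol_of(ch1.voxels.max() - ch1.voxels)
        _, rho = voxel_correlation(ch1, ch2, full_roi(ch1))
        assert rho == pytest.approx(-1.0)

    def test_ties_use_average_ranks(self):
        ch1 = vol_of([1.0, 2.0, 2.0, 3.0])
        ch2 = vol_of([1.0, 2.0, 3.0, 4.0])
        _, rho = voxel_correlation(ch1, ch2, full_roi(ch1))
        # oracle: average-rank then Pearson
        rx = stats.rankdata([1, 2, 2, 3])
        ry = stats.rankdata([1, 2, 3, 4])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_exact_linear_regression(self, rng):
        ch1 = vol_of(rng.random(50))
        ch2 = vol_of(2.0 * ch1.voxels + 3.0)
        slope, intercept = coloc_regression(ch1, ch2, full_roi(ch1))
        assert slope == pytest.approx(2.0) and intercept == pytest.approx(3.0)

    def test_noisy_ols_close_to_truth(self, rng):
        x = rng.uniform(0, 10, 1000)
        y = 0.8 * x + rng.normal(0, 1, 1000)
        slope, _ = coloc_regression(vol_of(x), vol_of(y), full_roi(vol_of(x)))
        se = 1.0 / np.sqrt(np.sum((x - x.mean()) ** 2))
        assert abs(slope - 0.8) <= 3 * se

    def test_constant_channel_rejected(self):
        ch1 = vol_of([1.0, 1.0, 1.0, 1.0])
        ch2 = vol_of([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            voxel_correlation(ch1, ch2, full_roi(ch1))


class TestRoiExclusivity:
    def test_out_of_roi_voxels_never_contribute(self, rng):
        shape = (10, 10, 10)
        ch1 = Volume(rng.integers(0, 100, shape).astype(float), (1, 1, 1))
        ch2 = Volume((0.7 * ch1.voxels + rng.normal(0, 5, shape)).clip(0), (1, 1, 1))
        roi_vox = rng.random(shape) > 0.5
        roi = BinaryMask(roi_vox, (1, 1, 1))
        base = colocalize(ch2, ch1, roi)
        corrupted1 = Volume(np.where(roi_vox, ch1.voxels, 1e6 * rng.random(shape)), (1, 1, 1))
        corrupted2 = Volume(np.where(roi_vox, ch2.voxels, -1e6 * rng.random(shape)), (1, 1, 1))
        after = colocalize(corrupted2, corrupted1, roi)
        assert after == base
        assert base.n_voxels == int(roi_vox.sum())
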