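import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from capdyn import cscp as cp
from capdyn.timeseries_io import RoiTimeseries, VoxelTimeseries


def profile(z, condition=""):
    z = np.atleast_2d(np.asarray(z, dtype=float))
    coords = np.column_stack([np.arange(z.shape[0]), np.zeros((z.shape[0], 2), int)])
    return cp.ProfileMatrix(z, coords, tuple(f"roi{i}" for i in range(z.shape[1])),
                            condition)


class TestConnectivityProfile:
    def test_attenuation_oracle_half_correlation(self, rng):
        """voxel = roi + noise of 3× the variance → population r = 1/√4 = 0.5."""
        n = 10_000
        roi = rng.standard_normal(n)
        vox = roi + np.sqrt(3) * rng.standard_normal(n)
        cortical = RoiTimeseries(roi[:, None], ("r0",), 2.0)
        striatal = VoxelTimeseries(vox[:, None], np.array([[0, 0, 0]]), 2.0)
        z = cp.connectivity_profile(striatal, cortical).z_values[0, 0]
        assert abs(z - np.arctanh(0.5)) < 3 / np.sqrt(n - 3) * 3

    def test_anticorrelated_sign(self, rng):
        roi = rng.standard_normal(300)
        vox = -roi + 0.5 * rng.standard_normal(300)
        cortical = RoiTimeseries(roi[:, None], ("r0",), 2.0)
        striatal = VoxelTimeseries(vox[:, None], np.array([[0, 0, 0]]), 2.0)
        assert cp.connectivity_profile(striatal, cortical).z_values[0, 0] < 0

    def test_identical_series_clipped_not_infinite(self, rng):
        x = rng.standard_normal(50)
        cortical = RoiTimeseries(x[:, None], ("r0",), 2.0)
        striatal = VoxelTimeseries(x[:, None], np.array([[0, 0, 0]]), 2.0)
        z = cp.connectivity_profile(striatal, cortical).z_values[0, 0]
        assert np.isfinite(z) and z > 5

    def test_zero_variance_voxel_flagged_nan(self, rng):
        vox = np.column_stack([np.ones(50), rng.standard_normal(50)])
        cortical = RoiTimeseries(rng.standard_normal((50, 2)), ("a", "b"), 2.0)
        striatal = VoxelTimeseries(vox, np.array([[0, 0, 0], [1, 0, 0]]), 2.0)
        z = cp.connectivity_profile(striatal, cortical).z_values
        assert np.isnan(z[0]).all() and np.isfinite(z[1]).all()


class TestAggregateDivergence:
    def test_identity_is_zero(self, rng):
        p = profile(rng.standard_normal((4, 6)))
        np.testing.assert_array_equal(cp.aggregate_divergence(p, p).values, 0)

    def test_hand_sum(self):
        a = profile([[0.9, 0.5]])
        b = profile([[0.5, 0.9]])
        assert cp.aggregate_divergence(a, b).values[0] == pytest.approx(0.8)

    def test_homogeneity_under_scaling(self, rng):
        za = rng.standard_normal((3, 5))
        zb = rng.standard_normal((3, 5))
        ad1 = cp.aggregate_divergence(profile(za), profile(zb)).values
        ad3 = cp.aggregate_divergence(profile(3 * za), profile(3 * zb)).values
        np.testing.assert_allclose(ad3, 3 * ad1)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            cp.aggregate_divergence(profile(rng.standard_normal((2, 3))),
                                    profile(rng.standard_normal((2, 4))))


class TestRankOrderRearrangement:
    def test_identity_is_zero(self, rng):
        p = profile(rng.standard_normal((5, 8)))
        np.testing.assert_array_equal(
            cp.rank_order_rearrangement(p, p).values, 0)

    def test_full_reversal_of_three(self):
        a = profile([[0.9, 0.5, 0.1]])
        b = profile([[0.1, 0.5, 0.9]])
        assert cp.rank_order_rearrangement(a, b).values[0] == 4

    @pytest.mark.parametrize("k", range(3, 11))
    def test_swap_of_two_weakest_is_two(self, k):
        z = np.linspace(1.0, 0.1, k)
        zb = z.copy()
        zb[-2], zb[-1] = zb[-1], zb[-2]
        val = cp.rank_order_rearrangement(profile(z), profile(zb)).values[0]
        assert val == 2

    @pytest.mark.parametrize("k", range(2, 11))
    def test_matches_rankdata_oracle(self, k, rng):
        """ROR equals a brute-force per-voxel ordinal-rank computation."""
        za = rng.standard_normal((6, k))
        zb = rng.standard_normal((6, k))
        got = cp.rank_order_rearrangement(profile(za), profile(zb)).values
        expected = [
            np.abs(rankdata(-za[v], method="ordinal")
                   - rankdata(-zb[v], method="ordinal")).sum()
            for v in range(6)
        ]
        np.testing.assert_array_equal(got, expected)

    @pytest.mark.parametrize("k", range(2, 8))
    def test_upper_bound_half_k_squared(self, k):
        """max over all permutations equals ⌊K²/2⌋, achieved by full reversal."""
        z = np.linspace(1.0, 0.0, k)
        base = profile(z)
        best = max(
            cp.rank_order_rearrangement(base, profile(z[list(perm)])).values[0]
            for perm in itertools.permutations(range(k))
        )
        assert best == k * k // 2
        reversal = cp.rank_order_rearrangement(base, profile(z[::-1].copy()))
        assert reversal.values[0] == k * k // 2

    def test_invariant_under_monotone_transform_unlike_ad(self, rng):
        za = rng.standard_normal((4, 6))
        zb = rng.standard_normal((4, 6))

        def mono(z):
            return np.sign(z) * np.log1p(np.abs(z)) * 2.0 + 0.1 * z

        ror1 = cp.rank_order_rearrangement(profile(za), profile(zb)).values
        ror2 = cp.rank_order_rearrangement(profile(mono(za)),
                                           profile(mono(zb))).values
        np.testing.assert_array_equal(ror1, ror2)
        ad1 = cp.aggregate_divergence(profile(za), profile(zb)).values
        ad2 = cp.aggregate_divergence(profile(mono(za)), profile(mono(zb))).values
        assert not np.allclose(ad1, ad2)


class TestEntropyShift:
    def test_identity_is_zero(self, rng):
        p = profile(rng.standard_normal((3, 7)))
        np.testing.assert_array_equal(cp.entropy_shift(p, p).values, 0)

    def test_uniform_profile_max_entropy(self):
        k = 9
        assert cp.profile_entropy(np.full(k, 0.4)) == pytest.approx(np.log(k))

    def test_dominant_vs_uniform_hand_evaluation(self):
        k = 5
        dominant = np.array([10.0, 1e-6, 1e-6, 1e-6, 1e-6])
        uniform = np.full(k, 0.3)
        es = cp.entropy_shift(profile(dominant), profile(uniform)).values[0]
        # direct numerical evaluation of the entropy difference
        w = np.abs(dominant) + 1e-12
        q = w / w.sum()
        h_dom = -(q * np.log(q)).sum()
        assert es == pytest.approx(np.log(k) - h_dom)
        assert es > 0

    def test_all_zero_row_floors_to_log_k(self):
        assert cp.profile_entropy(np.zeros(6)) == pytest.approx(np.log(6))


class TestSplitHalf:
    def test_split_arithmetic_235(self, rng):
        n = 235
        striatal = VoxelTimeseries(rng.standard_normal((n, 2)),
                                   np.array([[0, 0, 0], [1, 0, 0]]), 2.0)
        cortical = RoiTimeseries(rng.standard_normal((n, 3)),
                                 ("a", "b", "c"), 2.0)
        h1, h2 = cp.split_half_profiles(striatal, cortical)
        # internally frames 1..117 vs 118..235 — checked via determinism:
        manual1 = cp.connectivity_profile(
            VoxelTimeseries(striatal.values[:117], striatal.voxel_coords, 2.0),
            RoiTimeseries(cortical.values[:117], cortical.roi_names, 2.0))
        np.testing.assert_allclose(h1.z_values, manual1.z_values)
        manual2 = cp.connectivity_profile(
            VoxelTimeseries(striatal.values[117:], striatal.voxel_coords, 2.0),
            RoiTimeseries(cortical.values[117:], cortical.roi_names, 2.0))
        np.testing.assert_allclose(h2.z_values, manual2.z_values)

    def test_duplicated_half_gives_zero_divergence(self, rng):
        half = rng.standard_normal((30, 2))
        chalf = rng.standard_normal((30, 3))
        striatal = VoxelTimeseries(np.vstack([half, half]),
                                   np.array([[0, 0, 0], [1, 0, 0]]), 2.0)
        cortical = RoiTimeseries(np.vstack([chalf, chalf]),
                                 ("a", "b", "c"), 2.0)
        h1, h2 = cp.split_half_profiles(striatal, cortical)
        assert cp.aggregate_divergence(h1, h2).values.max() == 0
        assert cp.rank_order_rearrangement(h1, h2).values.max() == 0

    def test_too_few_frames(self, rng):
        striatal = VoxelTimeseries(rng.standard_normal((12, 1)),
                                   np.array([[0, 0, 0]]), 2.0)
        cortical = RoiTimeseries(rng.standard_normal((12, 2)), ("a", "b"), 2.0)
        with pytest.raises(ValueError):
            cp.split_half_profiles(striatal, cortical)


class TestSubjectScore:
    def test_constant_map(self):
        m = cp.CSCPMap("AD", np.full(5, 3.3),
                       np.column_stack([np.arange(5), np.zeros((5, 2), int)]))
        assert cp.subject_cscp_score(m) == pytest.approx(3.3)

    def test_subset_mean(self):
        coords = np.column_stack([np.arange(3), np.zeros((3, 2), int)])
        m = cp.CSCPMap("AD", np.array([1.0, 2.0, 3.0]), coords)
        assert cp.subject_cscp_score(m, coords[:2]) == pytest.approx(1.5)

    def test_partition_identity(self, rng):
        coords = np.column_stack([np.arange(10), np.zeros((10, 2), int)])
        vals = rng.standard_normal(10)
        m = cp.CSCPMap("ROR", vals, coords)
        s_all = cp.subject_cscp_score(m)
        s1 = cp.subject_cscp_score(m, coords[:4])
        s2 = cp.subject_cscp_score(m, coords[4:])
        assert s_all == pytest.approx((4 * s1 + 6 * s2) / 10)

    def test_empty_intersection_rejected(self):
        coords = np.column_stack([np.arange(3), np.zeros((3, 2), int)])
        m = cp.CSCPMap("AD", np.ones(3), coords)
        with pytest.raises(ValueError):
            cp.subject_cscp_score(m, np.array([[99, 99, 99]]))


class TestVoxelwisePairedTest:
    @staticmethod
    def _maps(values, coords):
        return [cp.CSCPMap("ROR", v, coords) for v in values]

    def test_identity_yields_empty_nodeset(self, rng):
        coords = np.column_stack([np.arange(20), np.zeros((20, 2), int)])
        vals = [rng.standard_normal(20) for _ in range(6)]
        nodes = cp.voxelwise_paired_test(self._maps(vals, coords),
                                         self._maps(vals, coords))
        assert len(nodes) == 0

    def test_planted_block_recovered_exactly(self, rng):
        # 4×4×4 grid, shift +1 in a contiguous 10-voxel block
        coords = np.array([(i, j, k) for k in range(4) for j in range(4)
                           for i in range(4)])
        n_vox = len(coords)
        block = np.arange(10)  # first 10 voxels are contiguous in the grid
        a_maps, b_maps = [], []
        for s in range(20):
            base = rng.standard_normal(n_vox) * 0.1
            b_maps.append(cp.CSCPMap("ROR", base, coords))
            shifted = base.copy()
            shifted[block] += 1.0
            a_maps.append(cp.CSCPMap("ROR", shifted, coords))
        nodes = cp.voxelwise_paired_test(a_maps, b_maps, p_threshold=0.001,
                                         min_extent=5)
        assert len(nodes) == 1
        assert sorted(map(tuple, nodes.nodes[0].coords)) == sorted(
            map(tuple, coords[block]))

    def test_t_values_match_closed_form(self, rng):
        coords = np.column_stack([np.arange(6), np.zeros((6, 2), int)])
        a = rng.standard_normal((8, 6))
        b = rng.standard_normal((8, 6))
        nodes = cp.voxelwise_paired_test(
            self._maps(a, coords), self._maps(b, coords),
            p_threshold=1.0, min_extent=1)
        d = a - b
        t_expected = d.mean(0) / (d.std(0, ddof=1) / np.sqrt(8))
        peak = max(nd.peak_t for nd in nodes)
        assert peak == pytest.approx(t_expected.max(), abs=1e-10)

    def test_too_few_subjects(self, rng):
        coords = np.column_stack([np.arange(4), np.zeros((4, 2), int)])
        maps = self._maps(rng.standard_normal((2, 4)), coords)
        with pytest.raises(ValueError):
            cp.voxelwise_paired_test(maps, maps)


class TestRankShiftSummary:
    def test_identity_profiles_empty_table(self, rng):
        z = rng.standard_normal((6, 10))
        p = profile(z)
        node = cp.StriatalNode(np.arange(3), p.voxel_coords[:3], 3, 1.0,
                               (0, 0, 0))
        assert len(cp.rank_shift_summary(node, p, p)) == 0

    def test_planted_six_rank_move(self):
        k = 10
        z = np.linspace(1.0, 0.1, k)
        # move the strongest ROI (index 0) down by exactly 6 ranks
        order = list(range(1, 7)) + [0] + list(range(7, k))
        zb = np.empty(k)
        zb[order] = z[np.argsort(-z)]  # reassign strengths to realize the move
        pa = profile(np.vstack([z, z]))
        pb = profile(np.vstack([zb, zb]))
        node = cp.StriatalNode(np.arange(2), pa.voxel_coords[:2], 2, 1.0,
                               (0, 0, 0))
        table = cp.rank_shift_summary(node, pa, pb, min_shift=5)
        assert "roi0" in set(table["roi"])
        row = table[table["roi"] == "roi0"].iloc[0]
        assert abs(row["mean_rank_shift"]) == 6

    def test_min_shift_zero_lists_every_roi(self, rng):
        za = rng.standard_normal((4, 7))
        zb = rng.standard_normal((4, 7))
        pa, pb = profile(za), profile(zb)
        node = cp.StriatalNode(np.arange(4), pa.voxel_coords, 4, 1.0, (0, 0, 0))
        assert len(cp.rank_shift_summary(node, pa, pb, min_shift=0)) == 7
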