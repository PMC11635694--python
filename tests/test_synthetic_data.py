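import numpy as np
import pytest

from capdyn import cap_dynamics as cd
from capdyn import synthetic_data as sd


class TestCentroids:
    def test_construction_contract(self):
        cs = sd.make_centroids(8, 129, seed=1)
        assert cs.values.shape == (8, 129)
        np.testing.assert_allclose(cs.values.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(cs.values.std(axis=1), 1, atol=1e-12)

    def test_pairwise_similarity_bounded(self):
        cs = sd.make_centroids(8, 129, seed=3)
        m = cs.values
        cos = (m @ m.T) / np.outer(np.linalg.norm(m, axis=1),
                                   np.linalg.norm(m, axis=1))
        np.fill_diagonal(cos, 0)
        assert np.abs(cos).max() <= 0.5

    def test_minimal_square_case_distinct(self):
        cs = sd.make_centroids(2, 2, seed=7)
        a, b = cs.values
        cos = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert abs(cos) < 1

    def test_seeded_determinism(self):
        a = sd.make_centroids(8, 129, seed=42).values
        b = sd.make_centroids(8, 129, seed=42).values
        np.testing.assert_array_equal(a, b)

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError):
            sd.make_centroids(5, 3, seed=0)


class TestStateSequence:
    def test_absorbing_identity_matrix(self):
        seq = sd.simulate_state_sequence(np.eye(4), 50, seed=9)
        assert len(set(seq.labels)) == 1

    def test_uniform_two_state_occupancy(self):
        """Empirical occupancy matches the stationary eigenvector oracle."""
        p = np.full((2, 2), 0.5)
        seq = sd.simulate_state_sequence(p, 100_000, seed=2)
        occ = (seq.labels == 1).mean()
        pi = sd.stationary_distribution(p)
        assert abs(occ - pi[0]) < 0.01
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_ergodic_occupancy_recovery(self):
        rng = np.random.default_rng(0)
        p = rng.random((5, 5)) + 0.05
        p /= p.sum(axis=1, keepdims=True)
        pi = sd.stationary_distribution(p)
        seq = sd.simulate_state_sequence(p, 100_000, seed=4)
        occ = np.array([(seq.labels == k + 1).mean() for k in range(5)])
        assert np.abs(occ - pi).max() < 0.01

    def test_seeded_determinism(self):
        p = sd.baseline_transition_matrix(8)
        a = sd.simulate_state_sequence(p, 235, seed=5).labels
        b = sd.simulate_state_sequence(p, 235, seed=5).labels
        np.testing.assert_array_equal(a, b)

    def test_non_stochastic_matrix_names_row(self):
        p = np.eye(3)
        p[1, 1] = 0.5
        with pytest.raises(ValueError, match="row 1"):
            sd.simulate_state_sequence(p, 10, seed=0)


class TestSubjectRun:
    def test_zero_noise_frames_equal_centroids(self, centroids8):
        seq = sd.simulate_state_sequence(
            sd.baseline_transition_matrix(8), 40, seed=3)
        run = sd.simulate_subject_run(centroids8, seq, noise_sd=0.0, seed=1)
        np.testing.assert_array_equal(
            run.values, centroids8.values[seq.labels - 1])

    def test_zero_noise_round_trip_assignment(self, centroids8):
        seq = sd.simulate_state_sequence(
            sd.baseline_transition_matrix(8), 235, seed=8)
        run = sd.simulate_subject_run(centroids8, seq, noise_sd=0.0, seed=2)
        recovered = cd.assign_frames(run, centroids8, normalize=False)
        np.testing.assert_array_equal(recovered.labels, seq.labels)

    def test_assignment_accuracy_at_study_noise(self, centroids8):
        """At the study noise level, assignment recovers >= 95% of labels."""
        accs = []
        for s in range(20):
            seq = sd.simulate_state_sequence(
                sd.baseline_transition_matrix(8), 235, seed=100 + s)
            run = sd.simulate_subject_run(centroids8, seq, noise_sd=0.5,
                                          seed=200 + s)
            lab = cd.assign_frames(run, centroids8)
            accs.append((lab.labels == seq.labels).mean())
        assert min(accs) >= 0.95

    def test_label_out_of_range(self, centroids8):
        seq = cd.StateLabelSequence(np.array([1, 9]), 2.0, 9)
        with pytest.raises(IndexError):
            sd.simulate_subject_run(centroids8, seq, 0.1, seed=0)


class TestStriatalRun:
    def test_one_hot_weights_copy_roi(self, centroids8):
        seq = sd.simulate_state_sequence(
            sd.baseline_transition_matrix(8), 30, seed=1)
        cortical = sd.simulate_subject_run(centroids8, seq, 0.3, seed=2)
        w = np.zeros((1, cortical.n_rois))
        w[0, 5] = 1.0
        vox = sd.simulate_striatal_run(cortical, w, noise_sd=0.0, seed=3)
        np.testing.assert_allclose(vox.values[:, 0], cortical.values[:, 5])

    def test_zero_weights_give_null_connectivity(self, centroids8):
        """Mean |z| against every ROI stays at null-sampling scale."""
        from capdyn.cscp import connectivity_profile

        zs = []
        for s in range(50):
            seq = sd.simulate_state_sequence(
                sd.baseline_transition_matrix(8), 235, seed=300 + s)
            cortical = sd.simulate_subject_run(centroids8, seq, 0.5, seed=400 + s)
            w = np.zeros((2, cortical.n_rois))
            vox = sd.simulate_striatal_run(cortical, w, noise_sd=1.0, seed=500 + s)
            prof = connectivity_profile(vox, cortical)
            zs.append(np.abs(prof.z_values).mean())
        assert np.mean(zs) < 0.1

    def test_dimension_mismatch(self, centroids8):
        seq = sd.simulate_state_sequence(
            sd.baseline_transition_matrix(8), 30, seed=1)
        cortical = sd.simulate_subject_run(centroids8, seq, 0.3, seed=2)
        with pytest.raises(ValueError):
            sd.simulate_striatal_run(cortical, np.ones((3, 7)), 0.1, seed=0)

    def test_permuted_weights_raise_ror(self, centroids8):
        """Planted permutation produces ROR > 0 at (nearly) zero noise."""
        from capdyn.cscp import connectivity_profile, rank_order_rearrangement
        from capdyn.timeseries_io import RoiTimeseries

        seq = sd.simulate_state_sequence(
            sd.baseline_transition_matrix(8), 235, seed=11)
        cortical = sd.simulate_subject_run(centroids8, seq, 0.2, seed=12)
        cortical53 = RoiTimeseries(cortical.values[:, :53],
                                   cortical.roi_names[:53], 2.0)
        w = sd.make_weight_profiles(4, 53, seed=13)
        w_perm, perms = sd.permute_weight_profiles(w, np.array([0, 2]), seed=14)
        v_a = sd.simulate_striatal_run(cortical53, w, 0.01, seed=15)
        v_b = sd.simulate_striatal_run(cortical53, w_perm, 0.01, seed=16)
        ror = rank_order_rearrangement(
            connectivity_profile(v_b, cortical53),
            connectivity_profile(v_a, cortical53),
        )
        # oracle: planted rank change from the permuted weights themselves
        assert ror.values[0] > 0 and ror.values[2] > 0
        assert set(perms) == {0, 2}


class TestCohort:
    def test_cohort_bookkeeping(self):
        cfg = sd.study_config(n_subjects=59, seed=0, n_striatal_voxels=4)
        cohort, truth = sd.simulate_cohort(cfg, include_striatal=False)
        assert len(cohort.roi_timeseries) == 177  # 59 subjects × 3 conditions
        assert len(cohort.manifest) == 177
        assert set(cohort.manifest["condition"]) == {"PBO", "MPH", "HAL"}
        ages = cohort.manifest["age"]
        assert ages.min() >= 18 and ages.max() <= 55

    def test_cohort_determinism(self):
        cfg1 = sd.study_config(n_subjects=3, seed=77, n_striatal_voxels=8)
        cfg2 = sd.study_config(n_subjects=3, seed=77, n_striatal_voxels=8)
        c1, _ = sd.simulate_cohort(cfg1)
        c2, _ = sd.simulate_cohort(cfg2)
        for key in c1.roi_timeseries:
            np.testing.assert_array_equal(
                c1.roi_timeseries[key].values, c2.roi_timeseries[key].values)
        for key in c1.striatal_timeseries:
            np.testing.assert_array_equal(
                c1.striatal_timeseries[key].values,
                c2.striatal_timeseries[key].values)

    def test_expected_dwell_sums_to_one(self):
        cfg = sd.study_config(n_subjects=2, seed=1, n_striatal_voxels=4)
        _, truth = sd.simulate_cohort(cfg, include_striatal=False)
        for pi in truth.expected_dwell.values():
            assert abs(pi.sum() - 1.0) < 1e-9

    def test_state_sequences_in_range(self):
        cfg = sd.study_config(n_subjects=2, seed=2, n_striatal_voxels=4)
        _, truth = sd.simulate_cohort(cfg, include_striatal=False)
        for seq in truth.state_sequences.values():
            assert seq.min() >= 1 and seq.max() <= 8

    def test_write_and_load_round_trip(self, tmp_path):
        cfg = sd.study_config(n_subjects=2, seed=3, n_striatal_voxels=8)
        cohort, truth = sd.simulate_cohort(cfg)
        sd.write_cohort(cohort, truth, tmp_path / "cohort")
        back = sd.load_cohort(tmp_path / "cohort")
        assert sorted(back.manifest["subject_id"]) == sorted(
            cohort.manifest["subject_id"])
        key = ("sub-001", "MPH")
        np.testing.assert_allclose(back.roi_timeseries[key].values,
                                   cohort.roi_timeseries[key].values,
                                   atol=1e-12)
        np.testing.assert_allclose(back.striatal_timeseries[key].values,
                                   cohort.striatal_timeseries[key].values,
                                   atol=1e-12)
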