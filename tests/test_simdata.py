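import numpy as np
import pytest
from scipy import stats

import orientwm as ow
from orientwm.simdata import (TARGET_SET, DISTRACTOR_SET, phase_grid,
                              _orientation_to_grid_index)
from orientwm.vmmm import VMMMParams


class TestDesign:
    def test_target_set_spans_shifted_grid(self):
        d = ow.generate_design(1, seed=0)
        targets = np.sort(d["target_deg"].to_numpy())
        assert targets[0] == pytest.approx(1.125)
        assert targets[-1] == pytest.approx(176.625)
        assert np.allclose(np.diff(targets), 4.5)

    def test_distractor_set_offset(self):
        d = ow.generate_design(1, seed=0)
        dist = np.sort(d["distractor_deg"].to_numpy())
        assert dist[0] == pytest.approx(3.375)
        assert dist[-1] == pytest.approx(178.875)
        assert not np.intersect1d(TARGET_SET, DISTRACTOR_SET).size

    def test_eight_runs_give_320_counterbalanced_trials(self, design8):
        assert len(design8) == 320
        counts = design8.groupby("target_deg").size()
        assert (counts == 8).all()
        # per-run balance: every orientation exactly once per run
        per_run = design8.groupby(["run", "target_deg"]).size()
        assert (per_run == 1).all()

    def test_avoids_cardinal_axes(self, design8):
        for col in ("target_deg", "distractor_deg"):
            vals = design8[col].to_numpy()
            assert not np.isin(vals, [0.0, 45.0, 90.0, 135.0]).any()

    def test_cue_values(self, design8):
        assert set(design8["cue"].unique()) <= {1, 2}


class TestKernel:
    def test_zero_lag_is_one(self):
        assert ow.periodic_kernel(0.3, 0.3, 0.7) == pytest.approx(1.0)

    def test_half_period_value(self):
        assert ow.periodic_kernel(0.0, np.pi, 1.0) == pytest.approx(
            np.exp(-2.0), rel=1e-12)

    def test_symmetry_and_periodicity(self, rng):
        a, b = rng.uniform(0, 2 * np.pi, 2)
        k = ow.periodic_kernel(a, b, 0.8)
        assert k == pytest.approx(ow.periodic_kernel(b, a, 0.8))
        assert k == pytest.approx(ow.periodic_kernel(a + 2 * np.pi, b, 0.8))
        assert 0.0 < k <= 1.0

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            ow.periodic_kernel(0.0, 1.0, 0.0)

    def test_kernel_matrix_psd_under_gamma_smoothness(self, rng):
        grid = phase_grid(40)
        for sigma in rng.gamma(2.0, 2.0, size=10):
            K = ow.periodic_kernel(grid[:, None], grid[None, :], sigma)
            assert np.linalg.eigvalsh(K).min() >= -1e-8


class TestTuningProfiles:
    def test_deterministic_under_seed(self):
        a = ow.sample_tuning_profiles(5, grid_size=40, seed=3)
        b = ow.sample_tuning_profiles(5, grid_size=40, seed=3)
        for p, q in zip(a, b):
            assert np.array_equal(p.values, q.values)
            assert p.smoothness == q.smoothness

    def test_shapes(self):
        profiles = ow.sample_tuning_profiles(12, grid_size=64, seed=4)
        assert len(profiles) == 12
        assert all(len(p.values) == 64 for p in profiles)
        assert all(p.smoothness > 0 for p in profiles)

    def test_unit_marginal_variance(self):
        # K(x, x) = 1 implies unit variance of z at every grid point
        profiles = ow.sample_tuning_profiles(1000, grid_size=16, seed=5)
        z = np.stack([p.values for p in profiles])
        var = z.var(axis=0)
        assert np.allclose(var, 1.0, atol=0.15)


class TestVoxelResponses:
    def test_pure_noise_at_zero_snr(self, design8):
        profiles = ow.sample_tuning_profiles(50, grid_size=90, seed=6)
        vox = ow.simulate_voxel_responses(profiles, design8, snr=0.0, seed=7)
        flat = vox.data.ravel()
        assert abs(flat.mean()) < 0.02
        assert abs(flat.var() - 1.0) < 0.03

    def test_deterministic_under_seed(self, design8):
        profiles = ow.sample_tuning_profiles(10, grid_size=90, seed=1)
        a = ow.simulate_voxel_responses(profiles, design8, snr=1.0, seed=2)
        b = ow.simulate_voxel_responses(profiles, design8, snr=1.0, seed=2)
        assert np.array_equal(a.data, b.data)

    def test_orientation_grid_mapping_error_bounded(self):
        idx = _orientation_to_grid_index(np.array([0.0, 90.0, 179.5]), 180)
        assert idx.tolist() == [0, 90, 0]  # 179.5° wraps to phase ~2π -> 0

    def test_rejects_out_of_range_orientation(self, design8):
        profiles = ow.sample_tuning_profiles(3, grid_size=90, seed=1)
        bad = design8.copy()
        bad.loc[0, "target_deg"] = 180.0
        with pytest.raises(ValueError):
            ow.simulate_voxel_responses(profiles, bad, snr=0.5, seed=0)


class TestExpandToTimecourse:
    def test_preserves_runs_and_onsets(self, small_signal_dataset):
        _, voxels, _ = small_signal_dataset
        tc = ow.expand_to_timecourse(voxels, trs_per_trial=6,
                                     active_window=(2, 4), seed=0)
        assert tc.layout == "timecourse"
        assert tc.n_runs == voxels.n_runs
        assert tc.onsets.shape == voxels.onsets.shape
        assert tc.data.shape[1] == voxels.data.shape[1] * 6

    def test_rejects_empty_or_bad_window(self, small_signal_dataset):
        _, voxels, _ = small_signal_dataset
        with pytest.raises(ValueError):
            ow.expand_to_timecourse(voxels, 6, (4, 2))
        with pytest.raises(ValueError):
            ow.expand_to_timecourse(voxels, 6, (0, 6))

    def test_signal_confined_to_active_window(self, small_signal_dataset):
        design, voxels, _ = small_signal_dataset
        series = ow.expand_to_timecourse(voxels, trs_per_trial=6,
                                         active_window=(2, 4), seed=11)
        tc = ow.reconstruct_timecourse(series, design,
                                       smoothing=ow.SmoothingSpec(0.0))
        acc = tc.bfca_per_tr()
        assert acc[2:5].min() > 60.0       # inside the window
        assert max(acc[0], acc[5]) < 57.0  # outside (TR 1 may bleed via MA-free design, none here)


class TestVoxelArrayIO:
    def test_roundtrip(self, small_signal_dataset, tmp_path):
        _, voxels, _ = small_signal_dataset
        voxels.save(tmp_path / "vox")
        back = ow.VoxelArray.load(tmp_path / "vox")
        assert np.array_equal(back.data, voxels.data)
        assert back.layout == voxels.layout
        assert np.array_equal(back.onsets, voxels.onsets)


class TestBehavior:
    def test_degenerate_detection_reproduces_targets(self, design8):
        # the kappa cap applies at fit time; simulation accepts large values
        params = VMMMParams(1.0, 0.0, 0.0, 1e6, 5.0, 0.0)
        out = ow.simulate_behavior(design8, params, seed=1)
        err = np.abs(ow.circ_diff_180(out["response_deg"], out["target_deg"]))
        assert err.max() < 0.5

    def test_guess_only_uniform(self):
        design = ow.generate_design(8, seed=2)
        big = design.sample(n=10000, replace=True, random_state=0)
        params = VMMMParams(0.0, 0.0, 1.0, 5.0, 5.0, 0.0)
        out = ow.simulate_behavior(big, params, seed=3)
        err = ow.circ_diff_180(out["response_deg"], out["target_deg"])
        # KS test against uniform on [-90, 90)
        stat = stats.kstest(err, stats.uniform(loc=-90, scale=180).cdf)
        assert stat.pvalue > 0.01

    def test_recovery_of_plausible_truth(self, design8):
        truth = VMMMParams(0.947, 0.028, 0.025, 5.673, 5.673, -0.889)
        out = ow.simulate_behavior(design8, truth, seed=4)
        fit = ow.fit_vmmm(out, n_restarts=6, seed=5)
        assert abs(fit.params.r1 - truth.r1) < 0.08
        assert abs(fit.params.kappa1 - truth.kappa1) < 2.0
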