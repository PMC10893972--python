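import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import orientwm as ow
from orientwm.preprocess import TrialSamples
from orientwm.psvr import (decode_labels, encode_labels,
                           fit_predict_pair, loro_cv, scale_across)


def _noise_free_toy(n=10, n_voxels=5, shift=0.0):
    """Trials whose features encode the orientation noiselessly."""
    theta = np.mod(np.linspace(0, 180, n, endpoint=False) + shift, 180.0)
    enc = encode_labels(theta)
    rng = np.random.default_rng(0)
    mix = rng.standard_normal((2, n_voxels))
    X = enc @ mix  # linear images of the sinusoid pair
    return X, theta


class TestEncodeDecode:
    @pytest.mark.parametrize("theta,pair", [
        (0.0, (0.0, 1.0)),
        (45.0, (1.0, 0.0)),
        (90.0, (0.0, -1.0)),
        (135.0, (-1.0, 0.0)),
    ])
    def test_encode_examples(self, theta, pair):
        assert np.allclose(encode_labels(theta), pair, atol=1e-12)

    @pytest.mark.parametrize("pair,theta", [
        ((0.0, 1.0), 0.0),
        ((1.0, 0.0), 45.0),
        ((0.0, -1.0), 90.0),
    ])
    def test_decode_examples(self, pair, theta):
        assert decode_labels(np.array(pair)) == pytest.approx(theta)

    def test_roundtrip_dense(self):
        theta = np.linspace(0, 180, 1000, endpoint=False)
        back = decode_labels(encode_labels(theta))
        assert np.abs(ow.circ_diff_180(back, theta)).max() < 1e-9

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.floats(0, 179.9999))
    def test_roundtrip_property(self, theta):
        assert abs(ow.circ_diff_180(
            decode_labels(encode_labels(theta)), theta)) < 1e-9

    def test_unit_norm_of_encoded(self):
        enc = encode_labels(np.linspace(0, 180, 50, endpoint=False))
        assert np.allclose((enc ** 2).sum(axis=1), 1.0, atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            decode_labels(np.zeros(2))

    def test_scale_invariance_of_decode(self):
        pair = encode_labels(77.0)
        assert decode_labels(3.7 * pair) == pytest.approx(77.0)


class TestScaleAcross:
    def test_train_to_unit_interval(self):
        train = np.array([[2.0], [4.0]])
        tr, te = scale_across(train, np.array([[3.0]]))
        assert np.allclose(tr.ravel(), [0.0, 1.0])
        assert te[0, 0] == pytest.approx(0.5)

    def test_test_may_exit_range(self):
        _, te = scale_across(np.array([[2.0], [4.0]]), np.array([[6.0]]))
        assert te[0, 0] == pytest.approx(2.0)

    def test_constant_feature_maps_to_zero(self):
        train = np.array([[1.0, 5.0], [1.0, 7.0]])
        test = np.array([[9.0, 6.0]])
        tr, te = scale_across(train, test)
        assert np.allclose(tr[:, 0], 0.0)
        assert te[0, 0] == 0.0
        assert te[0, 1] == pytest.approx(0.5)


class TestFitPredict:
    def test_fit_on_train_sanity(self):
        X, theta = _noise_free_toy()
        Xs, _ = scale_across(X, X)
        pairs = fit_predict_pair(Xs, encode_labels(theta), Xs)
        err = np.abs(ow.circ_diff_180(decode_labels(pairs), theta))
        assert err.mean() < 5.0

    @pytest.mark.parametrize("delta", [4.5, 45.0])
    def test_label_rotation_equivariance(self, delta):
        X, theta = _noise_free_toy(n=20)
        Xs, _ = scale_across(X, X)
        base = decode_labels(fit_predict_pair(Xs, encode_labels(theta), Xs))
        rotated = decode_labels(fit_predict_pair(
            Xs, encode_labels(np.mod(theta + delta, 180.0)), Xs))
        shift = ow.circ_diff_180(rotated, base)
        assert np.abs(ow.circ_diff_180(shift, delta)).max() < 1.0

    def test_identical_features_constant_prediction(self):
        X = np.ones((12, 4))
        theta = np.linspace(0, 180, 12, endpoint=False)
        pairs = fit_predict_pair(X, encode_labels(theta), X)
        assert np.allclose(pairs, pairs[0], atol=1e-10)

    def test_constant_labels_warn(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        pairs = np.tile(encode_labels(30.0), (10, 1))
        with pytest.warns(UserWarning, match="degenerate"):
            out = fit_predict_pair(X, pairs, X)
        assert np.allclose(out, pairs[0])

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_predict_pair(np.zeros((5, 3)), encode_labels(np.zeros(5)),
                             np.zeros((2, 4)))


class TestLoroCV:
    def test_each_trial_predicted_once(self, small_samples):
        preds = loro_cv(small_samples)
        assert preds.shape == (small_samples.n_trials,)
        assert np.all((preds >= 0) & (preds < 180))

    def test_eight_runs_eight_folds(self, design8):
        profiles = ow.sample_tuning_profiles(60, 90, seed=3)
        vox = ow.simulate_voxel_responses(profiles, design8, 1.0, seed=4)
        samples = ow.extract_trial_samples(vox, design8)
        preds = loro_cv(samples)
        assert len(preds) == 320

    def test_single_run_rejected(self):
        s = TrialSamples(np.random.default_rng(0).standard_normal((10, 3)),
                         np.linspace(0, 180, 10, endpoint=False),
                         np.ones(10))
        with pytest.raises(ValueError):
            loro_cv(s)

    def test_signal_gives_above_chance_accuracy(self, small_samples):
        acc = ow.bfca(small_samples.labels, loro_cv(small_samples))
        assert acc > 75.0

    def test_permuted_labels_are_at_chance(self):
        # null calibration: shuffled labels decode at ~50%
        design = ow.generate_design(4, seed=41)
        profiles = ow.sample_tuning_profiles(60, 90, seed=42)
        vox = ow.simulate_voxel_responses(profiles, design, 1.0, seed=43)
        samples = ow.extract_trial_samples(vox, design)
        rng = np.random.default_rng(44)
        accs = []
        for _ in range(20):
            shuffled = TrialSamples(samples.X,
                                    rng.permutation(samples.labels),
                                    samples.run_ids)
            accs.append(ow.bfca(samples.labels, loro_cv(shuffled)))
        assert abs(np.mean(accs) - 50.0) < 2.0


class TestReconstructTimecourse:
    def test_output_shape_and_frame(self, small_signal_dataset):
        design, voxels, _ = small_signal_dataset
        series = ow.expand_to_timecourse(voxels, 4, (1, 2), seed=5)
        tc = ow.reconstruct_timecourse(series, design,
                                       smoothing=ow.SmoothingSpec(40.0))
        assert tc.predictions.shape == (4, len(design))
        assert np.all((tc.predictions >= 0) & (tc.predictions < 180))
        frame = tc.to_frame()
        assert len(frame) == 4 * len(design)
        assert set(frame.columns) >= {"subject", "tr", "trial", "run",
                                      "label_kind", "true_deg",
                                      "predicted_deg"}

    def test_irrelevant_label_at_chance(self, small_signal_dataset):
        # signals are built from targets; distractor labels decode at chance
        design, voxels, _ = small_signal_dataset
        tc = ow.reconstruct_timecourse(voxels, design,
                                       label_kind="distractor")
        assert abs(tc.bfca_per_tr()[0] - 50.0) < 6.0

    def test_missing_label_column(self, small_signal_dataset):
        design, voxels, _ = small_signal_dataset
        with pytest.raises(KeyError):
            ow.reconstruct_timecourse(voxels, design.drop(columns=["probe_start_deg"]),
                                      label_kind="probe_start")
        with pytest.raises(ValueError):
            ow.reconstruct_timecourse(voxels, design, label_kind="nonsense")
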