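"""Conditioning chain: calibration, filtering, gravity, windows, SMOTE."""

import numpy as np
import pytest

from adaptimu import preprocessing as pp
from adaptimu import synthetic as sm


def _sine_stream(freq, duration=2.0, fs=200.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestCalibration:
    def test_identity_and_arithmetic(self):
        s = sm.generate_session(2, {"steady_running": 1.0}, 0, seed=0)
        ident = pp.CalibrationParams.identity(s.channels)
        np.testing.assert_array_equal(
            pp.correct_bias_scale(s, ident).values, s.values)
        calib = pp.CalibrationParams({c: 0.5 for c in s.channels},
                                     {c: 2.0 for c in s.channels})
        out = pp.correct_bias_scale(s, calib)
        np.testing.assert_allclose(out.values, (s.values - 0.5) * 2.0)

    def test_round_trip_through_inverse(self):
        s = sm.generate_session(2, {"steady_running": 1.0}, 0, seed=1)
        rng = np.random.default_rng(0)
        calib = pp.CalibrationParams(
            {c: float(rng.normal()) for c in s.channels},
            {c: float(rng.uniform(0.5, 2.0)) for c in s.channels})
        back = pp.correct_bias_scale(pp.correct_bias_scale(s, calib),
                                     calib.inverse())
        np.testing.assert_allclose(back.values, s.values, atol=1e-12)

    def test_missing_channel_and_bad_scale_rejected(self):
        s = sm.generate_session(1, {"steady_running": 1.0}, 0, seed=0)
        with pytest.raises(ValueError, match="missing"):
            pp.correct_bias_scale(s, pp.CalibrationParams({"acc_x": 0.0},
                                                          {"acc_x": 1.0}))
        with pytest.raises(ValueError, match="positive"):
            pp.CalibrationParams({"acc_x": 0.0}, {"acc_x": 0.0})


class TestLowpass:
    def test_dc_gain_unity(self):
        out = pp.lowpass_filter(np.full(400, 3.7))
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    def test_stopband_attenuation_80hz(self):
        """An 80 Hz tone (4x the 20 Hz cutoff) must be crushed below 1e-3:
        the 4th-order Butterworth applied forward and backward gives
        |H|^2 = 1/(1+(f/fc)^8), about 4e-5 at f/fc = 4."""
        out = pp.lowpass_filter(_sine_stream(80.0))
        assert np.abs(out[100:-100]).max() < 1e-3

    def test_passband_2hz_preserved(self):
        out = pp.lowpass_filter(_sine_stream(2.0, duration=4.0))
        amp = np.abs(out[200:-200]).max()
        assert abs(amp - 1.0) < 0.01

    def test_short_series_rejected_with_message(self):
        with pytest.raises(ValueError, match="warm-up"):
            pp.lowpass_filter(np.ones(10))

    def test_applies_to_acc_gyro_only(self):
        s = sm.generate_session(2, {"steady_running": 1.0}, 0, seed=0,
                                include_mag=True)
        out = pp.lowpass_stream(s)
        jm = s.channel_index("mag_x")
        np.testing.assert_array_equal(out.values[:, jm], s.values[:, jm])
        ja = s.channel_index("acc_x")
        assert not np.allclose(out.values[:, ja], s.values[:, ja])


class TestGravityRemoval:
    def test_static_sensor_zeroed(self):
        n = 400
        acc = np.tile([0.0, 0.0, 9.81], (n, 1))
        gyro = np.zeros((n, 3))
        lin = pp.remove_gravity(acc, gyro, dt=0.005)
        assert np.abs(lin).max() < 0.05

    def test_accel_only_limit_exact_after_one_step(self):
        acc = np.tile([0.0, 9.81, 0.0], (10, 1))
        lin = pp.remove_gravity(acc, np.zeros((10, 3)), dt=0.005, blend=1.0)
        np.testing.assert_allclose(lin[1:], 0.0, atol=1e-12)

    def test_slow_rotation_residual_bounded(self):
        """Constant 0.5 rad/s roll: gravity tracks the analytic rotating-
        frame solution; residual linear acceleration stays < 0.2 m/s^2."""
        fs, omega = 200.0, 0.5
        t = np.arange(int(6 * fs)) / fs
        # gravity direction in sensor frame rotating about x
        acc = 9.81 * np.column_stack(
            [np.zeros_like(t), np.sin(omega * t), np.cos(omega * t)])
        gyro = np.tile([omega, 0.0, 0.0], (t.size, 1))
        lin = pp.remove_gravity(acc, gyro, dt=1 / fs)
        assert np.linalg.norm(lin[-200:], axis=1).max() < 0.2

    def test_zero_norm_accel_falls_back_to_gyro(self):
        acc = np.tile([0.0, 0.0, 9.81], (5, 1))
        acc[2] = 0.0  # dead sample
        lin = pp.remove_gravity(acc, np.zeros((5, 3)), dt=0.005)
        assert np.isfinite(lin).all()


class TestResample:
    def test_uniform_input_identity(self):
        t = np.arange(100) / 200.0
        x = np.sin(t * 7)
        grid, out, valid = pp.resample_align(t, x[:, None])
        np.testing.assert_allclose(out[:, 0], x, atol=1e-12)
        assert valid.all()

    def test_linear_signal_exact_upsampling(self):
        t = np.arange(50) / 100.0
        ramp = 3.0 * t + 1.0
        grid, out, _ = pp.resample_align(t, ramp[:, None])
        np.testing.assert_allclose(out[:, 0], 3.0 * grid + 1.0, atol=1e-12)
        assert out[0, 0] == ramp[0] and abs(out[-1, 0] - ramp[-1]) < 1e-9

    def test_jittered_sine_interp_error_bound(self):
        rng = np.random.default_rng(4)
        t = np.sort(np.arange(0, 4, 0.005) + rng.uniform(-1e-3, 1e-3, 800))
        x = np.sin(2 * np.pi * 1.0 * t)
        grid, out, _ = pp.resample_align(t, x[:, None])
        assert np.abs(out[:, 0] - np.sin(2 * np.pi * grid)).max() < 0.01

    def test_long_gap_flagged_not_interpolated(self):
        t = np.concatenate([np.arange(0, 1, 0.005),
                            np.arange(1.5, 2.0, 0.005)])
        x = np.ones_like(t)
        _, _, valid = pp.resample_align(t, x[:, None], max_gap_s=0.1)
        assert (~valid).sum() > 0

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            pp.resample_align(np.array([0.0, 0.1, 0.1]), np.zeros((3, 1)))


class TestWindowing:
    @pytest.mark.parametrize("n_samples, expected", [
        (200, 9), (40, 1), (38, 0), (239, 10), (240, 11)])
    def test_window_count_formula(self, n_samples, expected):
        """floor((n - 40) / 20) + 1 windows for an n-sample 200 Hz stream."""
        s = sm.LabeledImuStream(200.0, list(sm.BASE_CHANNELS),
                                np.zeros((n_samples, 6)))
        ws = pp.segment_windows(s)
        assert len(ws) == expected
        if expected:
            starts = [round(w.start_s * 200) for w in ws]
            assert starts == list(range(0, n_samples - 39, 20))

    def test_risk_labeling_with_overlap(self):
        """Event at 2.0 s: windows starting 1.8 and 1.9 s are risk (>= 50 %
        overlap with the pre-injury 200 ms segment); 2.0 s is not."""
        s = sm.LabeledImuStream(200.0, list(sm.BASE_CHANNELS),
                                np.zeros((800, 6)))
        ws = pp.segment_windows(s)
        pp.label_risk_windows(ws, [sm.InjuryEvent(2.0, "inversion")])
        risk_starts = sorted(round(w.start_s, 3) for w in ws if w.label == 1)
        assert risk_starts == [1.8, 1.9]

    def test_no_events_all_no_risk(self):
        s = sm.generate_session(4, {"steady_running": 1.0}, 0, seed=0)
        ws = pp.label_risk_windows(pp.segment_windows(s), [])
        assert all(w.label == 0 for w in ws)

    def test_early_event_warns(self):
        s = sm.LabeledImuStream(200.0, list(sm.BASE_CHANNELS),
                                np.zeros((400, 6)))
        ws = pp.segment_windows(s)
        with pytest.warns(UserWarning, match="incomplete"):
            pp.label_risk_windows(ws, [sm.InjuryEvent(0.1, "impact")])


class TestNormalization:
    def _windows(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        return [pp.MotionWindow(rng.normal(2.0, 3.0, (40, 6)), i * 0.1)
                for i in range(n)]

    def test_train_set_self_normalizes_to_unit(self):
        ws = self._windows()
        stats = pp.compute_norm_stats(ws)
        normed = pp.z_normalize(ws, stats)
        stacked = np.concatenate([w.x for w in normed])
        np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(stacked.std(axis=0), 1.0, atol=1e-9)

    def test_identity_stats(self):
        ws = self._windows()
        stats = pp.NormStats(np.zeros(6), np.ones(6), split="train")
        normed = pp.z_normalize(ws, stats)
        np.testing.assert_array_equal(normed[0].x, ws[0].x)

    def test_test_split_stats_rejected(self):
        ws = self._windows()
        stats = pp.NormStats(np.zeros(6), np.ones(6), split="test")
        with pytest.raises(ValueError, match="leakage|train"):
            pp.z_normalize(ws, stats)

    def test_held_out_windows_keep_offset(self):
        stats = pp.compute_norm_stats(self._windows(seed=1))
        held = pp.z_normalize(self._windows(seed=99), stats)
        stacked = np.concatenate([w.x for w in held])
        assert np.abs(stacked.mean(axis=0)).max() > 1e-4

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="degenerate|positive"):
            pp.NormStats(np.zeros(6), np.zeros(6))


class TestRebalance:
    def _imbalanced(self, n_maj=100, n_min=10, seed=0):
        rng = np.random.default_rng(seed)
        X = np.concatenate([rng.normal(0, 1, (n_maj, 40, 6)),
                            rng.normal(3, 1, (n_min, 40, 6))])
        y = np.array([0] * n_maj + [1] * n_min)
        return X, y

    def test_smote_to_parity(self):
        X, y = self._imbalanced()
        Xb, yb, w = pp.rebalance_training(X, y, seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 100
        np.testing.assert_allclose(w, [1.0, 1.0])

    def test_balanced_input_unchanged(self):
        X, y = self._imbalanced(50, 50)
        Xb, yb, w = pp.rebalance_training(X, y)
        assert Xb.shape[0] == 100
        np.testing.assert_array_equal(w, [1.0, 1.0])

    def test_synthetic_samples_are_convex_combinations(self):
        """Every synthetic vector lies on a segment between two real
        minority vectors (checked against nearest-pair decompositions)."""
        X, y = self._imbalanced(40, 8, seed=3)
        Xb, yb, _ = pp.rebalance_training(X, y, seed=3)
        Xmin = X[y == 1].reshape(8, -1)
        synth = Xb[len(y):].reshape(-1, 240 * (Xb.shape[2] // 6))
        synth = Xb[len(y):].reshape(len(Xb) - len(y), -1)
        for v in synth[:10]:
            # v = a + g (b - a) => residual after projecting onto (b - a)
            ok = False
            for i in range(8):
                for j in range(8):
                    if i == j:
                        continue
                    d = Xmin[j] - Xmin[i]
                    g = float(np.dot(v - Xmin[i], d) / np.dot(d, d))
                    if -1e-9 <= g <= 1 + 1e-9 and np.allclose(
                            Xmin[i] + g * d, v, atol=1e-8):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_single_minority_sample_weights_only(self):
        X, y = self._imbalanced(30, 1)
        with pytest.warns(UserWarning, match="SMOTE skipped"):
            Xb, yb, w = pp.rebalance_training(X, y)
        assert Xb.shape[0] == 31
        assert w[1] > w[0]

    def test_single_class_rejected(self):
        X = np.zeros((10, 40, 6))
        with pytest.raises(ValueError, match="both classes"):
            pp.rebalance_training(X, np.zeros(10, dtype=int))


def test_subject_split_fractions():
    splits = pp.split_subjects(list(range(20)), seed=0)
    assert len(splits["train"]) == 14
    assert len(splits["val"]) == 2
    assert len(splits["test"]) == 4
    all_ids = np.concatenate([splits[k] for k in ("train", "val", "test")])
    assert sorted(all_ids.tolist()) == list(range(20))
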