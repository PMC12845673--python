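"""Tilt estimation, joint kinematics, filtering, normalisation, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bracekin import JointCurve, NormalizedCurve, SimulationConfig, kinematics as kin
from bracekin.curves import SegmentAngleSeries
from bracekin.errors import (
    CalibrationError,
    OrientationError,
    PairingError,
    ParameterError,
    QuantityMismatchError,
)
from bracekin.profiles import generate_adl_profile
from bracekin.simulate import simulate_imu, simulate_trial


class TestTilt:
    @pytest.mark.parametrize(
        "ax,ay,expected",
        [(0, 1, 0.0), (1, 0, 90.0), (-1, 0, -90.0), (0, -1, 180.0), (1, 1, 45.0)],
    )
    def test_four_quadrant_convention(self, ax, ay, expected):
        assert kin.estimate_tilt(ax, ay) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(OrientationError):
            kin.estimate_tilt(0.0, 0.0)

    @settings(max_examples=100, derandomize=True)
    @given(angle=st.floats(min_value=-179.9, max_value=180.0))
    def test_tilt_inverts_gravity_projection(self, angle):
        rad = np.radians(angle)
        assert kin.estimate_tilt(np.sin(rad), np.cos(rad)) == pytest.approx(angle, abs=1e-9)


class TestStaticReference:
    def _standing_recording(self, thigh_deg, shank_deg, cfg):
        prof = generate_adl_profile("sit", peak_flexion_deg=30.0, duration_s=2.0)
        from bracekin.io import SENSOR_SEGMENT, BraceRecording

        rec = BraceRecording(nominal_rate_hz=cfg.brace_rate_hz, activity_name="sit")
        mounts = {"thigh": thigh_deg, "shank": shank_deg}
        rng = np.random.default_rng(0)
        for sid, seg in SENSOR_SEGMENT.items():
            t, acc, gyr = simulate_imu(prof, seg, cfg, rng=rng, mount_offset_deg=mounts[seg])
            rec.t[sid], rec.accel[sid], rec.gyro[sid] = t, acc, gyr
        return rec

    def test_offsets_recovered_and_joint_zeroed(self):
        """Standing at thigh 2 deg / shank -3 deg yields those offsets, so
        the referenced standing joint angle is ~0."""
        cfg = SimulationConfig(seed=0).noise_free()
        rec = self._standing_recording(2.0, -3.0, cfg)
        offsets = kin.static_reference(rec, window_s=1.0)
        assert offsets["thigh"] == pytest.approx(2.0, abs=0.01)
        assert offsets["shank"] == pytest.approx(-3.0, abs=0.01)
        assert offsets["thigh"] - offsets["shank"] - 5.0 == pytest.approx(0.0, abs=0.02)

    def test_gyro_activity_raises_calibration_error(self):
        cfg = SimulationConfig(seed=0).noise_free()
        rec = self._standing_recording(0.0, 0.0, cfg)
        rec.gyro["above_knee"][:, 2] = 131 * 50  # 50 deg/s spin in the window
        with pytest.raises(CalibrationError):
            kin.static_reference(rec, window_s=1.0)

    def test_noisy_standing_offset_within_two_degrees(self):
        """Monte-Carlo over 100 seeds: 1 s of 20 Hz standing with 0.05 g
        accelerometer noise localises the reference within 2 deg."""
        errs = []
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, accel_noise_g=0.05, gyro_noise_dps=0.5,
                gyro_bias_dps=0.0, soft_tissue_amp_deg=0.0, mount_offset_sd_deg=0.0,
                mocap_noise_deg=0.0, start_offset_s=(0.0, 0.0),
            )
            rec = self._standing_recording(5.0, 0.0, cfg)
            offsets = kin.static_reference(rec, window_s=1.0)
            errs.append(abs(offsets["thigh"] - 5.0))
        assert np.max(errs) < 2.0


def _series(t, vals, segment="thigh"):
    return SegmentAngleSeries(t=np.asarray(t, float), tilt_deg=np.asarray(vals, float), segment=segment)


class TestJointAngleVelocity:
    def test_thigh_minus_shank(self):
        t = np.arange(5) * 0.05
        th = _series(t, np.full(5, 10.0))
        sh = _series(t, np.full(5, -20.0), "shank")
        np.testing.assert_allclose(kin.joint_angle(th, sh).value, 30.0)

    def test_identical_series_give_zero(self):
        t = np.arange(5) * 0.05
        s = np.sin(t) * 30
        np.testing.assert_allclose(
            kin.joint_angle(_series(t, s), _series(t, s, "shank")).value, 0.0, atol=1e-12
        )

    @settings(max_examples=50, derandomize=True)
    @given(c=st.floats(min_value=-90, max_value=90))
    def test_common_offset_invariance(self, c):
        """Adding a constant to both segments leaves the joint unchanged
        (reference-offset independence)."""
        t = np.arange(10) * 0.05
        a = np.linspace(0, 40, 10)
        b = np.linspace(5, -20, 10)
        base = kin.joint_angle(_series(t, a), _series(t, b, "shank")).value
        shifted = kin.joint_angle(_series(t, a + c), _series(t, b + c, "shank")).value
        np.testing.assert_allclose(shifted, base, atol=1e-9)

    def test_velocity_difference(self):
        t = np.arange(4) * 0.05
        th = JointCurve(t=t, value=np.full(4, 50.0), quantity="velocity", rate_hz=20)
        sh = JointCurve(t=t, value=np.full(4, -30.0), quantity="velocity", rate_hz=20)
        np.testing.assert_allclose(kin.joint_velocity(th, sh).value, 80.0)

    def test_non_overlapping_ranges_rejected(self):
        a = _series([0, 1], [0, 0])
        b = _series([5, 6], [0, 0], "shank")
        from bracekin.errors import AlignmentError

        with pytest.raises(AlignmentError):
            kin.joint_angle(a, b)


class TestButterworth:
    def _sine(self, freq, rate=200.0, dur=5.0):
        t = np.arange(int(dur * rate)) / rate
        return t, JointCurve(t=t, value=np.sin(2 * np.pi * freq * t), quantity="angle", rate_hz=rate)

    def test_dc_gain_unity(self):
        t = np.arange(200) / 200.0
        c = JointCurve(t=t, value=np.full(200, 7.0), quantity="angle", rate_hz=200)
        np.testing.assert_allclose(kin.butterworth_zero_lag(c, 6.0).value, 7.0, atol=1e-9)

    def test_passband_amplitude_and_zero_lag(self):
        """1 Hz sine through a 6 Hz double-pass filter: analytic gain
        (1/(1+(f/fc)^8))^... applied twice stays within 1 % of unity, and
        peaks do not shift."""
        t, c = self._sine(1.0)
        out = kin.butterworth_zero_lag(c, 6.0)
        mid = slice(200, 800)
        gain = np.max(np.abs(out.value[mid]))
        assert gain == pytest.approx(1.0, abs=0.01)
        # zero lag: peak positions coincide up to the 1 s period
        dt_peak = t[mid][np.argmax(out.value[mid])] - t[mid][np.argmax(c.value[mid])]
        assert min(abs(dt_peak) % 1.0, 1.0 - abs(dt_peak) % 1.0) < 1e-6

    def test_stopband_attenuation(self):
        t, c = self._sine(50.0)
        out = kin.butterworth_zero_lag(c, 6.0)
        assert np.max(np.abs(out.value[200:800])) < 0.01  # > 99 % attenuation

    def test_cutoff_above_nyquist_rejected(self):
        _, c = self._sine(1.0)
        with pytest.raises(ParameterError):
            kin.butterworth_zero_lag(c, 120.0)


class TestOutliers:
    def _curves(self, peaks):
        t = np.arange(50) * 0.05
        return [
            JointCurve(t=t, value=p * np.sin(np.pi * t / t[-1]), quantity="angle", rate_hz=20)
            for p in peaks
        ]

    def test_identical_trials_kept(self):
        kept, log = kin.remove_outlier_trials(self._curves([60] * 5))
        assert len(kept) == 5 and not log.removed

    def test_single_extreme_trial_removed(self):
        """Hand-evaluated MAD rule: peaks (60,61,59,60,160) have median 60,
        scaled MAD 1.4826; only 160 exceeds 3x."""
        kept, log = kin.remove_outlier_trials(self._curves([60, 61, 59, 60, 160]))
        assert len(kept) == 4
        assert log.removed[0][0] == 4

    def test_two_trials_rejected(self):
        with pytest.raises(PairingError):
            kin.remove_outlier_trials(self._curves([60, 61]))

    def test_over_forty_percent_removal_keeps_all_flagged(self):
        kept, log = kin.remove_outlier_trials(
            self._curves([60, 61, 59, 60, 160, 170, 180])
        )
        assert len(kept) == 7 and log.flagged


class TestNormalization:
    def test_constant_curve(self):
        t = np.arange(40) * 0.05
        c = JointCurve(t=t, value=np.full(40, 3.0), quantity="angle", rate_hz=20)
        out = kin.time_normalize(c, 0, 39)
        np.testing.assert_allclose(out.value, 3.0)

    def test_linear_ramp_preserved(self):
        t = np.arange(77) * 0.05
        c = JointCurve(t=t, value=np.linspace(0, 100, 77), quantity="angle", rate_hz=20)
        out = kin.time_normalize(c, 0, 76)
        np.testing.assert_allclose(out.value, np.arange(101.0), atol=1e-9)

    def test_sine_against_analytic_resampling(self):
        """20 Hz sine segment resampled onto the cycle grid agrees with the
        analytic sine to < 0.1 deg."""
        t = np.arange(0, 2.0001, 0.05)
        c = JointCurve(t=t, value=30 * np.sin(np.pi * t / 2.0), quantity="angle", rate_hz=20)
        out = kin.time_normalize(c, 0, t.size - 1)
        analytic = 30 * np.sin(np.pi * (np.arange(101) / 100.0))
        assert np.max(np.abs(out.value - analytic)) < 0.1

    def test_idempotent_on_cycle_grid(self):
        t = np.arange(101) / 100.0
        vals = np.sin(t * 3)
        c = JointCurve(t=t, value=vals, quantity="angle", rate_hz=100)
        out = kin.time_normalize(c, 0, 100)
        np.testing.assert_allclose(out.value, vals, atol=1e-12)

    def test_bad_indices(self):
        t = np.arange(10) * 0.05
        c = JointCurve(t=t, value=np.zeros(10), quantity="angle", rate_hz=20)
        with pytest.raises(IndexError):
            kin.time_normalize(c, 0, 50)
        with pytest.raises(ParameterError):
            kin.time_normalize(c, 3, 4)


class TestEnsemble:
    def test_identical_curves_zero_sd(self):
        c = NormalizedCurve(value=np.sin(np.arange(101) / 10), quantity="angle")
        mean, sd = kin.ensemble_average([c, c, c])
        np.testing.assert_allclose(mean.value, c.value)
        np.testing.assert_array_equal(sd, 0.0)

    def test_matches_bruteforce_loop(self, rng):
        curves = [
            NormalizedCurve(value=rng.normal(size=101), quantity="angle") for _ in range(50)
        ]
        mean, sd = kin.ensemble_average(curves)
        for j in range(101):
            col = [c.value[j] for c in curves]
            assert mean.value[j] == pytest.approx(sum(col) / 50, abs=1e-12)
            m = sum(col) / 50
            var = sum((x - m) ** 2 for x in col) / 49
            assert sd[j] == pytest.approx(var**0.5, abs=1e-12)

    def test_mixed_quantities_rejected(self):
        a = NormalizedCurve(value=np.zeros(101), quantity="angle")
        b = NormalizedCurve(value=np.zeros(101), quantity="velocity")
        with pytest.raises(QuantityMismatchError):
            kin.ensemble_average([a, b])


class TestAlignment:
    def _shifted_pair(self, lag):
        t_b = np.arange(0, 8, 0.05)
        sig = np.exp(-((t_b - 4.0) ** 2)) * 60
        brace = JointCurve(t=t_b, value=sig, quantity="angle", rate_hz=20)
        t_m = np.arange(0, 10, 0.005)
        moc = JointCurve(
            t=t_m, value=np.exp(-((t_m - lag - 4.0) ** 2)) * 60, quantity="angle", rate_hz=200
        )
        return brace, moc

    @pytest.mark.parametrize("true_lag", [0.0, 0.5])
    def test_lag_recovered_within_one_brace_sample(self, true_lag):
        brace, moc = self._shifted_pair(true_lag)
        lag, _, crit = kin.align_streams(brace, moc)
        assert lag == pytest.approx(true_lag, abs=0.05)
        np.testing.assert_allclose(crit.value, brace.value[: crit.value.size], atol=1.0)

    def test_uncorrelated_streams_fail(self):
        t = np.arange(0, 8, 0.05)
        rng = np.random.default_rng(0)
        brace = JointCurve(t=t, value=np.sin(2 * np.pi * 5 * t), quantity="angle", rate_hz=20)
        moc = JointCurve(t=t, value=rng.normal(size=t.size), quantity="angle", rate_hz=20)
        from bracekin.errors import AlignmentError

        with pytest.raises(AlignmentError):
            kin.align_streams(brace, moc)

    def test_monte_carlo_offset_recovery(self):
        """Simulated trials with random offsets in [0, 1] s at default
        noise: lag error <= 0.1 s in >= 95 % of 200 seeds."""
        ok = 0
        n = 200
        for seed in range(n):
            cfg = SimulationConfig(seed=seed)
            rng = np.random.default_rng(seed)
            prof = generate_adl_profile("walk")
            tr = simulate_trial(prof, cfg, rng)
            from bracekin.pipeline import process_trial, PipelineConfig

            tc = process_trial(tr, PipelineConfig())
            if abs(tc.lag_s - tr.offset_s) <= 0.1:
                ok += 1
        assert ok / n >= 0.95


class TestPeak:
    def test_monotone_ramp_peaks_at_end(self):
        c = NormalizedCurve(value=np.arange(101.0), quantity="angle")
        assert kin.extract_peak(c) == (100.0, 100.0)

    def test_symmetric_bump_peaks_at_half(self):
        c = NormalizedCurve(value=np.sin(np.pi * np.arange(101) / 100.0), quantity="angle")
        assert kin.extract_peak(c)[1] == 50.0

    def test_tie_broken_earliest(self):
        v = np.zeros(101)
        v[30] = v[70] = 5.0
        c = NormalizedCurve(value=v, quantity="angle")
        assert kin.extract_peak(c) == (5.0, 30.0)
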