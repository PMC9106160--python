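import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitevents import (
    angular_velocity,
    lowpass_filter,
    segment_orientation,
    shank_signal_from_markers,
)
from gaitevents.errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    ValidationError,
)
from gaitevents.simulate import generate_velocity_waveform
from gaitevents.types import MarkerTrial


def quadrant_arctan(dy: float, dx: float) -> float:
    """Independent four-quadrant angle oracle built on plain math.atan."""
    if dx > 0:
        return math.atan(dy / dx)
    if dx < 0:
        return math.atan(dy / dx) + (math.pi if dy >= 0 else -math.pi)
    return math.pi / 2 if dy > 0 else -math.pi / 2


class TestSegmentOrientation:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            ((0.0, 1.0), (0.0, 0.6), np.pi / 2),  # vertical segment
            ((1.0, 1.0), (0.0, 0.0), np.pi / 4),
            ((0.3, 1.2), (0.1, 0.4), 1.3258176636680326),
        ],
    )
    def test_known_angles(self, p1, p2, expected):
        assert segment_orientation(np.array(p1), np.array(p2)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_matches_quadrant_arctan_oracle(self):
        rng = np.random.default_rng(42)
        p1 = rng.normal(0, 1, (1000, 2))
        p2 = rng.normal(0, 1, (1000, 2))
        got = segment_orientation(p1, p2)
        want = [quadrant_arctan(a[1] - b[1], a[0] - b[0]) for a, b in zip(p1, p2)]
        assert np.max(np.abs(got - want)) < 1e-12

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            segment_orientation(np.array([0.5, 0.5]), np.array([0.5, 0.5]))

    @given(
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(-100, 100),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, dx, dy, ox, oy):
        p1 = np.array([0.3 + dx, 1.2 + dy])
        p2 = np.array([0.1, 0.4])
        if np.allclose(p1, p2):
            return
        offset = np.array([ox, oy])
        assert segment_orientation(p1 + offset, p2 + offset) == pytest.approx(
            segment_orientation(p1, p2), abs=1e-9
        )


class TestAngularVelocity:
    def test_constant_angle_gives_zero(self):
        omega = angular_velocity(np.full(100, 0.5), fs=200)
        assert np.allclose(omega, 0.0)

    def test_linear_ramp(self):
        t = np.arange(200) / 200
        omega = angular_velocity(2.0 * t, fs=200)
        assert np.allclose(omega[1:-1], 2.0)

    def test_sinusoid_matches_closed_form(self):
        fs = 200
        t = np.arange(2 * fs) / fs
        theta = 0.3 * np.sin(2 * np.pi * t)
        omega = angular_velocity(theta, fs)
        expected = 0.3 * 2 * np.pi * np.cos(2 * np.pi * t)
        rms = np.sqrt(np.mean((omega[1:-1] - expected[1:-1]) ** 2))
        assert rms / np.sqrt(np.mean(expected**2)) < 1e-3

    def test_too_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            angular_velocity(np.array([0.1, 0.2]), fs=200)


class TestLowpassFilter:
    def test_dc_gain_is_unity(self):
        out = lowpass_filter(np.full(500, 5.0), fs=200)
        assert np.allclose(out, 5.0)

    def test_passband_amplitude_and_phase(self):
        fs = 200
        t = np.arange(4 * fs) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = lowpass_filter(x, fs)
        core = slice(fs, 3 * fs)
        assert abs(np.max(y[core]) - 1.0) < 0.01
        # zero phase: peak positions shift by at most one sample
        xp = np.argmax(x[core])
        yp = np.argmax(y[core])
        assert abs(xp - yp) <= 1

    def test_stopband_attenuation(self):
        fs = 200
        t = np.arange(4 * fs) / fs
        x = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 40.0 * t)
        y = lowpass_filter(x, fs)
        residual = y - lowpass_filter(np.sin(2 * np.pi * 1.0 * t), fs)
        assert np.max(np.abs(residual[fs:-fs])) < 0.01

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValidationError):
            lowpass_filter(np.zeros(100), fs=200, fc=120)

    def test_zero_phase_cross_correlation(self):
        fs = 200
        t = np.arange(6 * fs) / fs
        x = np.sin(2 * np.pi * 1.5 * t) + 0.5 * np.sin(2 * np.pi * 0.7 * t + 1.0)
        y = lowpass_filter(x, fs)
        lags = np.arange(-10, 11)
        xc = [np.dot(x[fs : -fs], np.roll(y, k)[fs : -fs]) for k in lags]
        assert lags[int(np.argmax(xc))] == 0


class TestShankSignalFromMarkers:
    def test_recovers_generator_velocity(self, noiseless_trial, noiseless_config):
        sig = shank_signal_from_markers(noiseless_trial.markers, "sound")
        omega_true, _ = generate_velocity_waveform(noiseless_config, "sound")
        core = slice(200, -200)
        err = sig.omega[core] - omega_true[core]
        rel_rms = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(omega_true[core] ** 2))
        assert rel_rms < 0.02

    def test_translation_invariance(self, noiseless_trial):
        base = shank_signal_from_markers(noiseless_trial.markers, "sound")
        shifted = {
            label: arr + np.array([0.3, -1.2, 2.5]) for label, arr in noiseless_trial.markers.markers.items()
        }
        trial2 = MarkerTrial(
            trial_id="t",
            fs=noiseless_trial.markers.fs,
            markers=shifted,
            axis_map=noiseless_trial.markers.axis_map,
        )
        moved = shank_signal_from_markers(trial2, "sound")
        assert np.allclose(moved.theta, base.theta, atol=1e-9)
        assert np.allclose(moved.omega, base.omega, atol=1e-9)

    def test_swapped_markers_shift_theta_by_pi(self, noiseless_trial, config):
        base = shank_signal_from_markers(noiseless_trial.markers, "sound")
        cfg = type(config)(
            proximal_markers={"sound": "STIBI"}, distal_markers={"sound": "STIB"}
        )
        swapped = shank_signal_from_markers(noiseless_trial.markers, "sound", cfg)
        dtheta = np.abs(np.abs(swapped.theta - base.theta) - np.pi) % (2 * np.pi)
        assert np.max(np.minimum(dtheta, 2 * np.pi - dtheta)) < 1e-6
        assert np.allclose(swapped.omega, base.omega, atol=1e-6)

    def test_missing_marker_named_in_error(self, noiseless_trial):
        with pytest.raises(ValidationError, match="LTIB"):
            shank_signal_from_markers(noiseless_trial.markers, "left")

    def test_filter_differentiation_commute(self, noiseless_trial):
        # band-limited input: filtering then differentiating matches
        # differentiating then filtering (both linear, zero-phase)
        fs = noiseless_trial.markers.fs
        sig = shank_signal_from_markers(noiseless_trial.markers, "prosthetic")
        from gaitevents.kinematics import angular_velocity as diff, lowpass_filter as lp

        a = lp(diff(sig.theta, fs), fs)
        b = diff(lp(sig.theta, fs), fs)
        core = slice(int(fs), -int(fs))
        rel = np.sqrt(np.mean((a[core] - b[core]) ** 2)) / np.sqrt(np.mean(a[core] ** 2))
        assert rel < 0.01

    def test_mirrored_lab_frame_auto_oriented(self, noiseless_trial):
        mirrored = {
            label: arr * np.array([1.0, -1.0, 1.0])
            for label, arr in noiseless_trial.markers.markers.items()
        }
        trial2 = MarkerTrial(
            trial_id="m", fs=noiseless_trial.markers.fs, markers=mirrored
        )
        sig = shank_signal_from_markers(trial2, "sound")
        base = shank_signal_from_markers(noiseless_trial.markers, "sound")
        # midswing peaks point upward in both
        assert np.max(sig.omega) > abs(np.min(sig.omega))
        assert np.max(base.omega) > abs(np.min(base.omega))
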