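import logging

import numpy as np
import pytest

from gaitevents import (
    DetectionConfig,
    detect_midswing,
    detect_to_hs,
    grf_reference_events,
    zero_crossing_to,
)
from gaitevents.errors import ValidationError
from gaitevents.events import detect_events
from gaitevents.kinematics import shank_signal_from_markers
from gaitevents.types import FORCE, HS, KINEMATIC, MS, TO, ForceTrial, GaitEvent


def _single_swing(fs=200.0, n=400):
    """One synthetic swing hump: dip, positive peak, dip."""
    t = np.arange(n) / fs
    omega = (
        6.0 * np.exp(-(((t - 1.0) / 0.08) ** 2))
        - 2.0 * np.exp(-(((t - 0.7) / 0.05) ** 2))
        - 2.0 * np.exp(-(((t - 1.3) / 0.05) ** 2))
    )
    return omega, t


class TestDetectMidswing:
    def test_simulator_peaks_within_one_sample(self, noiseless_trial, noiseless_config):
        fs = noiseless_trial.markers.fs
        for side in noiseless_config.sides:
            sig = shank_signal_from_markers(noiseless_trial.markers, side)
            ms = detect_midswing(sig.omega, fs, side)
            hs_true, _ = noiseless_config.truth_times(side)
            _, d_ms, _ = noiseless_config.stride_landmarks(side)
            expected = hs_true[:-1] + d_ms
            assert len(ms) == noiseless_config.n_cycles
            err = np.abs(np.array([e.time_s for e in ms]) - expected)
            assert np.max(err) <= 1.0 / fs + 1e-9

    def test_all_zero_signal_gives_empty_list(self):
        assert detect_midswing(np.zeros(1000), 200.0) == []

    def test_single_hump_gives_one_event(self):
        omega, _ = _single_swing()
        ms = detect_midswing(omega, 200.0)
        assert len(ms) == 1
        assert ms[0].time_s == pytest.approx(1.0, abs=0.01)

    def test_nan_rejected(self):
        omega = np.zeros(100)
        omega[10] = np.nan
        with pytest.raises(ValidationError):
            detect_midswing(omega, 200.0)

    def test_scale_invariance(self, noiseless_trial):
        sig = shank_signal_from_markers(noiseless_trial.markers, "sound")
        base = detect_midswing(sig.omega, sig.fs, "sound")
        scaled = detect_midswing(3.7 * sig.omega, sig.fs, "sound")
        assert [e.time_s for e in base] == [e.time_s for e in scaled]


class TestDetectToHs:
    def test_simulator_minima_within_one_sample(self, noiseless_trial, noiseless_config):
        fs = noiseless_trial.markers.fs
        for side in noiseless_config.sides:
            sig = shank_signal_from_markers(noiseless_trial.markers, side)
            events = detect_events(sig)
            hs_true, to_true = noiseless_config.truth_times(side)
            d_to, _, d_hs = noiseless_config.stride_landmarks(side)
            to_det = [e.time_s for e in events if e.kind == TO]
            hs_det = [e.time_s for e in events if e.kind == HS]
            assert len(to_det) == len(to_true)
            assert np.max(np.abs(np.array(to_det) - (hs_true[:-1] + d_to))) <= 1 / fs + 1e-9
            assert np.max(np.abs(np.array(hs_det) - (hs_true[:-1] + d_hs))) <= 1 / fs + 1e-9

    def test_cycle_ordering_to_ms_hs(self, noiseless_trial):
        sig = shank_signal_from_markers(noiseless_trial.markers, "sound")
        events = detect_events(sig)
        by_cycle = {}
        for e in events:
            by_cycle.setdefault(e.cycle_index, {})[e.kind] = e.time_s
        complete = [c for c in by_cycle.values() if set(c) == {MS, TO, HS}]
        assert complete, "no complete cycles detected"
        for c in complete:
            assert c[TO] < c[MS] < c[HS]

    def test_unsorted_ms_events_rejected(self):
        omega, _ = _single_swing()
        ms = [
            GaitEvent(time_s=1.5, kind=MS, side="x"),
            GaitEvent(time_s=1.0, kind=MS, side="x"),
        ]
        with pytest.raises(ValidationError):
            detect_to_hs(omega, 200.0, ms)

    def test_boundary_ms_without_preceding_minimum(self):
        # MS at the very first sample: no preceding minimum, so no TO for
        # that cycle; the following minimum still yields the HS
        fs = 200.0
        t = np.arange(300) / fs
        omega = 6.0 * np.exp(-((t / 0.08) ** 2)) - 2.0 * np.exp(
            -(((t - 0.4) / 0.05) ** 2)
        )
        ms = [GaitEvent(time_s=0.0, kind=MS, side="x", cycle_index=0)]
        events = detect_to_hs(omega, fs, ms)
        kinds = [e.kind for e in events]
        assert TO not in kinds
        assert HS in kinds

    def test_shared_minimum_between_peaks_logged(self, caplog):
        # two MS peaks with exactly one negative minimum between them
        fs = 200.0
        t = np.arange(500) / fs
        omega = (
            6.0 * np.exp(-(((t - 0.6) / 0.08) ** 2))
            + 6.0 * np.exp(-(((t - 1.8) / 0.08) ** 2))
            - 2.0 * np.exp(-(((t - 1.2) / 0.06) ** 2))
            - 2.0 * np.exp(-(((t - 0.2) / 0.05) ** 2))
            - 2.0 * np.exp(-(((t - 2.2) / 0.05) ** 2))
        )
        ms = detect_midswing(omega, fs)
        assert len(ms) == 2
        with caplog.at_level(logging.WARNING, logger="gaitevents.events"):
            events = detect_to_hs(omega, fs, ms)
        hs0 = [e for e in events if e.kind == HS and e.cycle_index == 0]
        to1 = [e for e in events if e.kind == TO and e.cycle_index == 1]
        assert hs0 and to1 and hs0[0].time_s == to1[0].time_s
        assert any("single negative minimum" in r.message for r in caplog.records)


class TestZeroCrossing:
    def test_linear_interpolation_midpoint(self):
        fs = 200.0
        omega = np.full(60, -1.0)
        omega[21:] = 1.0  # -1 at sample 20 (0.100 s), +1 at sample 21 (0.105 s)
        to = GaitEvent(time_s=0.09, kind=TO, side="x", source=KINEMATIC)
        zc = zero_crossing_to(omega, fs, to)
        assert zc.time_s == pytest.approx(0.1025, abs=1e-9)

    def test_simulator_cycle_ordering(self, noiseless_trial):
        sig = shank_signal_from_markers(noiseless_trial.markers, "sound")
        events = detect_events(sig)
        tos = [e for e in events if e.kind == TO]
        mss = {e.cycle_index: e.time_s for e in events if e.kind == MS}
        for to in tos[:5]:
            zc = zero_crossing_to(sig.omega, sig.fs, to, until_s=mss[to.cycle_index])
            assert zc is not None
            assert to.time_s < zc.time_s < mss[to.cycle_index]

    def test_positive_immediately_after_to(self):
        fs = 200.0
        omega = np.concatenate([[-0.5], np.ones(30)])
        to = GaitEvent(time_s=0.0, kind=TO, side="x", source=KINEMATIC)
        zc = zero_crossing_to(omega, fs, to)
        assert 0.0 < zc.time_s <= 1.0 / fs

    def test_no_crossing_returns_none(self):
        omega = np.full(50, -1.0)
        to = GaitEvent(time_s=0.0, kind=TO, side="x", source=KINEMATIC)
        assert zero_crossing_to(omega, 200.0, to) is None

    def test_wrong_event_kind_rejected(self):
        with pytest.raises(ValidationError):
            zero_crossing_to(np.zeros(10), 200.0, GaitEvent(time_s=0.0, kind=HS, side="x"))


class TestGrfReferenceEvents:
    def test_constructed_trapezoid_crossings(self):
        fs = 1000.0
        t = np.arange(int(2.5 * fs)) / fs
        fz = np.interp(t, [0, 1.0, 1.1, 1.6, 1.8, 2.5], [0, 0, 500, 500, 0, 0])
        force = ForceTrial(trial_id="t", fs=fs, fz={"left": fz})
        events = grf_reference_events(force, "left")
        # linear rise 0->500 over [1.0, 1.1] crosses 20 N at 1.004; fall
        # 500->0 over [1.6, 1.8] crosses 20 N at 1.792
        assert [e.kind for e in events] == [HS, TO]
        assert events[0].time_s == pytest.approx(1.004, abs=1e-6)
        assert events[1].time_s == pytest.approx(1.792, abs=1e-6)

    def test_zero_force_gives_empty_list(self):
        force = ForceTrial(trial_id="t", fs=1000.0, fz={"left": np.zeros(1000)})
        assert grf_reference_events(force, "left") == []

    def test_simulator_truth_within_one_sample(self, noiseless_trial, noiseless_config):
        for side in noiseless_config.sides:
            events = grf_reference_events(noiseless_trial.force, side)
            hs_true, to_true = noiseless_config.truth_times(side)
            hs_det = [e.time_s for e in events if e.kind == HS]
            to_det = [e.time_s for e in events if e.kind == TO]
            assert len(hs_det) == len(hs_true)
            assert np.max(np.abs(np.array(hs_det) - hs_true)) <= 1e-3
            assert np.max(np.abs(np.array(to_det) - to_true)) <= 1e-3

    def test_alternation_and_source(self, noiseless_trial):
        events = grf_reference_events(noiseless_trial.force, "sound")
        kinds = [e.kind for e in events]
        assert kinds == [HS, TO] * (len(kinds) // 2) + ([HS] if len(kinds) % 2 else [])
        assert all(e.source == FORCE for e in events)
        times = [e.time_s for e in events]
        assert times == sorted(times)

    def test_chatter_debounced(self):
        fs = 1000.0
        fz = np.zeros(3000)
        fz[1000:2000] = 500.0
        fz[1490:1500] = 0.0  # 10 ms dropout inside stance
        force = ForceTrial(trial_id="t", fs=fs, fz={"left": fz})
        events = grf_reference_events(force, "left")
        assert [e.kind for e in events] == [HS, TO]

    def test_missing_side_rejected(self, noiseless_trial):
        with pytest.raises(ValidationError, match="left"):
            grf_reference_events(noiseless_trial.force, "left")
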