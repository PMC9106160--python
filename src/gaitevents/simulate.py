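"""Synthetic bilateral gait trials with ground-truth events.

The generator emulates the structure of treadmill mocap data from unilateral
transfemoral amputees: per leg, a shank sagittal angular-velocity waveform
with one dominant positive midswing (MS) peak per stride flanked by two
negative minima, tibia marker trajectories consistent with that waveform,
a vertical ground-reaction force supporting each stance phase, and the
force-defined ground-truth heel-strike/toe-off times.

Waveform construction.  Each stride contributes three cosine-squared bumps
on a small positive baseline: a negative dip whose minimum marks
(true TO − to_min_lead), a dominant positive midswing peak, and a negative
dip at (true HS + hs_min_lag).  The bump train is smoothed with a zero-phase
low-pass (3.5 Hz) so the emitted waveform is band-limited well inside the
4 Hz band the detection stage preserves, and the bump centres and amplitudes
are *calibrated* by fixed-point iteration so that the smoothed waveform's
extrema sit exactly on the configured landmark times with the configured
peak amplitude.  The configurable lead of the toe-off minimum relative to
true toe-off injects the early-TO bias the dual-minima rule shows on real
amputee gait (larger on the sound side by default); the small heel-strike
lag injects the slightly-late HS detection.  These defaults are study
conditions for exercising the method, not biomechanical claims.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq, root
from scipy.signal import butter, filtfilt

from .cycles import params_from_events
from .errors import ConfigError
from .types import (
    FORCE,
    HS,
    TO,
    AxisMap,
    ForceTrial,
    GaitEvent,
    MarkerTrial,
    TemporalParams,
)

__all__ = ["SyntheticConfig", "SyntheticTrial", "generate_velocity_waveform", "generate_trial"]

PerSide = Union[float, Mapping[str, float]]

# waveform shape constants (fractions of stride time / peak amplitude);
# wide bumps keep the smoothed waveform band-limited so the detection
# filter leaves its extrema in place (see docs/methods.md)
_NP_WIDTH_FRAC = 0.20    # negative-dip half-width / stride time
_MS_WIDTH_FRAC = 0.28    # midswing-bump half-width / stride time
_NP_DEPTH_FRAC = 0.55    # dip depth / midswing amplitude
_BASE_FRAC = 0.07        # stance baseline / midswing amplitude
_SMOOTH_CYCLES_PER_STRIDE = 3.8   # smoothing cutoff = this / stride time (Hz)
_SMOOTH_ORDER = 4

# the standard shank-velocity measurement chain the markers are built for:
# central-difference differentiation followed by a 4 Hz zero-phase low-pass
_CHAIN_CUTOFF_HZ = 4.0
_CHAIN_ORDER = 4


def _smoothing_cutoff_hz(stride_s: float) -> float:
    """Generator smoothing cutoff: fixed number of cycles per stride.

    ≈3.5 Hz at the default 55 strides/min; scaling with cadence keeps the
    waveform shape identical across walking speeds.
    """
    return _SMOOTH_CYCLES_PER_STRIDE / stride_s

_calibration_cache: dict[tuple, tuple] = {}


def _per_side(value: PerSide, side: str, name: str) -> float:
    if isinstance(value, Mapping):
        if side not in value:
            raise ConfigError(f"{name} has no entry for side {side!r}")
        return float(value[side])
    return float(value)


@dataclass
class SyntheticConfig:
    """Conditions of a synthetic gait trial.

    Defaults describe moderate-speed amputee treadmill walking: stride time
    60/55 ≈ 1.09 s, stance fractions 62% (sound) / 60% (prosthetic), a
    6 rad/s midswing peak, toe-off velocity minima leading true toe-off by
    80 ms (sound) / 35 ms (prosthetic), heel-strike minima lagging true
    heel strike by 5 / 13 ms, and 2 mm marker noise emulating soft-tissue
    artifact.  Markers sample at 200 Hz, force at 1000 Hz.
    """

    n_cycles: int = 10
    cadence_spm: float = 55.0          # strides per minute
    stance_fraction: PerSide = field(
        default_factory=lambda: {"sound": 0.62, "prosthetic": 0.60}
    )
    ms_peak_amp: float = 6.0           # rad/s
    to_min_lead_ms: PerSide = field(
        default_factory=lambda: {"sound": 80.0, "prosthetic": 35.0}
    )
    hs_min_lag_ms: PerSide = field(
        default_factory=lambda: {"sound": 5.0, "prosthetic": 13.0}
    )
    marker_noise_std_m: float = 0.002
    fs_markers: float = 200.0
    fs_force: float = 1000.0
    seed: int = 0
    sides: Sequence[str] = ("sound", "prosthetic")
    body_weight_n: float = 750.0
    shank_length_m: float = 0.4
    trial_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError(f"n_cycles must be >= 1, got {self.n_cycles}")
        if self.cadence_spm <= 0:
            raise ConfigError(f"cadence_spm must be > 0, got {self.cadence_spm}")
        if self.ms_peak_amp <= 0:
            raise ConfigError("ms_peak_amp must be > 0")
        if self.fs_markers <= 0 or self.fs_force <= 0:
            raise ConfigError("sampling rates must be > 0")
        for side in self.sides:
            self.stride_landmarks(side)  # validates ordering

    # ---- timing helpers -------------------------------------------------
    @property
    def stride_s(self) -> float:
        return 60.0 / self.cadence_spm

    def side_offset(self, side: str) -> float:
        """Phase offset of a side's strides; legs alternate by half a stride."""
        return self.sides.index(side) * self.stride_s / 2.0

    @property
    def lead_in_s(self) -> float:
        return 0.5 * self.stride_s

    @property
    def duration_s(self) -> float:
        last_offset = max(self.side_offset(s) for s in self.sides)
        return self.lead_in_s + last_offset + self.n_cycles * self.stride_s + 0.5 * self.stride_s

    def stride_landmarks(self, side: str) -> tuple[float, float, float]:
        """Velocity-landmark offsets within one stride: (TO dip, MS peak, HS dip).

        Measured from stride start (the heel strike).  The TO dip precedes
        true toe-off by ``to_min_lead``; the HS dip follows the *next* heel
        strike (at one stride time) by ``hs_min_lag``.

        Raises ConfigError when the lead/lag squeeze the landmarks out of
        order for the configured stance/swing durations.
        """
        T = self.stride_s
        f = _per_side(self.stance_fraction, side, "stance_fraction")
        if not 0 < f < 1:
            raise ConfigError(f"stance_fraction for {side!r} must be in (0,1), got {f}")
        lead = _per_side(self.to_min_lead_ms, side, "to_min_lead_ms") / 1000.0
        lag = _per_side(self.hs_min_lag_ms, side, "hs_min_lag_ms") / 1000.0
        if lead < 0:
            raise ConfigError("to_min_lead_ms must be >= 0")
        d_to = f * T - lead
        d_ms = f * T + 0.5 * (1 - f) * T
        d_hs = T + lag
        swing = (1 - f) * T
        if not (0.15 * T < d_to and d_ms < d_hs and lag < 0.25 * swing and lead < 0.6 * f * T):
            raise ConfigError(
                f"landmarks out of order for side {side!r}: to_min_lead={lead * 1000:.0f} ms "
                f"/ hs_min_lag={lag * 1000:.0f} ms too large for stance {f * T:.3f} s, "
                f"swing {swing:.3f} s"
            )
        return d_to, d_ms, d_hs

    def truth_times(self, side: str) -> tuple[np.ndarray, np.ndarray]:
        """Ground-truth (HS, TO) times for a side: n+1 heel strikes, n toe-offs."""
        T = self.stride_s
        start = self.lead_in_s + self.side_offset(side)
        f = _per_side(self.stance_fraction, side, "stance_fraction")
        hs = start + np.arange(self.n_cycles + 1) * T
        to = hs[:-1] + f * T
        return hs, to


@dataclass
class SyntheticTrial:
    """A generated trial: markers, force, and the ground truth behind them."""

    markers: MarkerTrial
    force: ForceTrial
    truth_events: list[GaitEvent]
    truth_params: list[TemporalParams]
    config: SyntheticConfig


def _bump(t: np.ndarray, center: float, halfwidth: float, amp: float) -> np.ndarray:
    """Compact cosine-squared bump: amp at center, zero outside ±halfwidth."""
    u = (np.asarray(t) - center) / halfwidth
    out = np.zeros_like(np.asarray(t, dtype=float))
    inside = np.abs(u) < 1
    out[inside] = amp * np.cos(0.5 * np.pi * u[inside]) ** 2
    return out


def _bump_train(
    t: np.ndarray,
    stride_starts: Sequence[float],
    centers: Sequence[float],
    amps: Sequence[float],
    widths: Sequence[float],
    base: float,
) -> np.ndarray:
    w = np.full_like(np.asarray(t, dtype=float), base)
    for s in stride_starts:
        for c, a, hw in zip(centers, amps, widths):
            w += _bump(t, s + c, hw, a)
    return w


def _parabolic_time(y: np.ndarray, i: int, dt: float) -> float:
    """Sub-sample extremum time by parabolic interpolation around index i."""
    den = y[i - 1] - 2 * y[i] + y[i + 1]
    if den == 0:
        return i * dt
    return (i + (y[i - 1] - y[i + 1]) / (2 * den)) * dt


def _calibrate_bumps(
    T: float, d_to: float, d_ms: float, d_hs: float, amp: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Bump centres/amplitudes whose smoothed extrema hit the landmarks.

    Works on a periodic 10-stride signal at 1 kHz: place bumps, smooth with
    the generator filter, locate each extremum near its target (parabolic
    interpolation), and move the bump centres and scale the amplitudes until
    every extremum sits on its landmark (<0.1 ms) with the prescribed values
    (MS = amp, dips = −0.55·amp, within 2%).  The fixed point is cached per
    parameter set.  Raises ConfigError if the iteration cannot converge —
    the landmark layout is then too tight for a resolvable waveform.
    """
    key = (round(T, 6), round(d_to, 6), round(d_ms, 6), round(d_hs, 6), round(amp, 6))
    if key in _calibration_cache:
        return _calibration_cache[key]
    base = _BASE_FRAC * amp
    depth = _NP_DEPTH_FRAC * amp
    gap = min(d_ms - d_to, d_hs - d_ms)
    targets = np.array([d_to, d_ms, d_hs])
    signs = np.array([-1.0, 1.0, -1.0])
    goal = np.array([-depth, amp, -depth])

    fg = 1000.0
    m = 10
    t = np.arange(int(m * T * fg)) / fg
    starts = [k * T for k in range(-1, m + 1)]
    b, a = butter(_SMOOTH_ORDER, _smoothing_cutoff_hz(T), btype="low", fs=fg)
    k0 = m // 2
    rng = np.random.default_rng(0)  # deterministic restart perturbations
    # full-width bumps keep the waveform band-limited (no detection-filter
    # shift); gap-capped and shrunk variants are fallbacks for tight layouts
    candidates = [(_NP_WIDTH_FRAC * T, _MS_WIDTH_FRAC * T)]
    for shrink in (1.0, 0.7, 0.5):
        candidates.append(
            (
                min(_NP_WIDTH_FRAC * T, 0.9 * gap) * shrink,
                min(_MS_WIDTH_FRAC * T, 1.1 * gap) * shrink,
            )
        )
    for w_np, w_ms in candidates:
        widths = np.array([w_np, w_ms, w_np])
        amps0 = np.array([-(depth + base), amp - base, -(depth + base)])

        def residual(x: np.ndarray) -> np.ndarray:
            centers = targets + x[:3]
            amps = amps0 * np.exp(x[3:])
            w = filtfilt(b, a, _bump_train(t, starts, centers, amps, widths, base))
            res = np.zeros(6)
            for j, (tg, sg, gl) in enumerate(zip(targets, signs, goal)):
                i0 = int(round((k0 * T + tg) * fg))
                r = int(0.12 * fg)
                seg = (w * sg)[i0 - r : i0 + r]
                i = int(np.argmax(seg)) + i0 - r
                res[j] = _parabolic_time(w * sg, i, 1 / fg) - (k0 * T + tg)
                res[3 + j] = (w[i] - gl) / abs(gl)
            return res

        for attempt in range(3):
            x0 = (
                np.zeros(6)
                if attempt == 0
                else np.concatenate([rng.normal(0, 0.01, 3), rng.normal(0, 0.1, 3)])
            )
            sol = root(residual, x0, method="hybr", options={"xtol": 1e-10})
            res = residual(sol.x)
            if np.max(np.abs(res[:3])) < 1e-4 and np.max(np.abs(res[3:])) < 0.02:
                result = (targets + sol.x[:3], amps0 * np.exp(sol.x[3:]), widths, base)
                _calibration_cache[key] = result
                return result
    raise ConfigError(
        f"cannot realise a waveform with landmarks TO-dip {d_to:.3f} s, "
        f"MS {d_ms:.3f} s, HS-dip {d_hs:.3f} s in a {T:.3f} s stride; "
        "the features are too close to resolve"
    )


def generate_velocity_waveform(
    config: SyntheticConfig, side: str
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Noise-free shank angular velocity for one side, plus landmark times.

    Returns the rad/s series sampled at ``fs_markers`` over the whole trial
    and a dict of absolute landmark times: true events ``HS``/``TO`` and the
    velocity landmarks ``MS``, ``NP_TO`` (toe-off minimum) and ``NP_HS``
    (heel-strike minimum).  Per cycle the waveform has exactly one dominant
    positive peak and two negative minima; the smoothed dip shoulders give
    the small stance-phase undulation.
    """
    T = config.stride_s
    d_to, d_ms, d_hs = config.stride_landmarks(side)
    centers, amps, widths, base = _calibrate_bumps(T, d_to, d_ms, d_hs, config.ms_peak_amp)
    fs = config.fs_markers
    t = np.arange(int(round(config.duration_s * fs)) + 1) / fs
    hs, to = config.truth_times(side)
    starts = hs[:-1]
    b, a = butter(_SMOOTH_ORDER, _smoothing_cutoff_hz(T), btype="low", fs=fs)
    omega = filtfilt(b, a, _bump_train(t, starts, centers, amps, widths, base))
    landmarks = {
        "HS": hs,
        "TO": to,
        "MS": starts + d_ms,
        "NP_TO": starts + d_to,
        "NP_HS": starts + d_hs,
    }
    return omega, landmarks


def _precompensate(omega_designed: np.ndarray, fs: float) -> np.ndarray:
    """Velocity to integrate into marker angles so the standard measurement
    chain recovers the designed waveform.

    Differentiating the marker angle (central difference) and low-pass
    filtering at 4 Hz attenuates the designed waveform's upper band slightly
    and thereby shifts its extrema by a few milliseconds — the ground-truth
    landmarks would no longer be where the truth table says.  This damped
    fixed-point iteration solves chain(omega_pre) = omega_designed; the
    result is a mildly sharpened waveform (a few percent), analogous to raw
    versus filtered velocity of real marker data.  The iteration is
    self-regularising: bands the chain suppresses entirely are left at the
    designed amplitude rather than amplified.
    """
    b, a = butter(_CHAIN_ORDER, _CHAIN_CUTOFF_HZ, btype="low", fs=fs)

    def chain(om: np.ndarray) -> np.ndarray:
        theta = cumulative_trapezoid(om, dx=1 / fs, initial=0.0)
        return filtfilt(b, a, np.gradient(theta, 1 / fs))

    omega_pre = omega_designed.copy()
    for _ in range(6):
        omega_pre = omega_pre + (omega_designed - chain(omega_pre))
    return omega_pre


def _grf_series(config: SyntheticConfig, side: str) -> np.ndarray:
    """Vertical GRF: a smoothed trapezoid over each true stance interval.

    Ramps use a cubic smoothstep and are shifted so the force crosses the
    20 N convention threshold exactly at the true heel-strike and toe-off
    instants (any threshold below ~10% body weight crosses within the ramp).
    """
    fs = config.fs_force
    n = int(round(config.duration_s * fs)) + 1
    t = np.arange(n) / fs
    fz = np.zeros(n)
    W = config.body_weight_n
    ramp = 0.08  # s
    thr = 20.0 / W

    def smoothstep(u: np.ndarray) -> np.ndarray:
        u = np.clip(u, 0.0, 1.0)
        return 3 * u**2 - 2 * u**3

    u0 = brentq(lambda u: 3 * u**2 - 2 * u**3 - thr, 0.0, 0.5)
    hs, to = config.truth_times(side)
    # one stance per toe-off, plus a trailing partial stance after the final
    # heel strike so the reference stream contains all n+1 heel strikes
    stance_ends = list(to) + [t[-1] + 1.0]
    for h, end in zip(hs, stance_ends):
        up = smoothstep((t - (h - u0 * ramp)) / ramp)
        down = smoothstep(((end + u0 * ramp) - t) / ramp)
        fz += W * np.minimum(up, down)
    return fz


def generate_trial(config: SyntheticConfig | None = None) -> SyntheticTrial:
    """Generate a full synthetic trial from a config.

    The shank angle is the running integral of the velocity waveform; the
    proximal and distal tibia markers sit on a rigid segment of length
    ``shank_length_m`` rotated by that angle about an ankle point that
    oscillates gently with the stride, with i.i.d. Gaussian positional noise
    of ``marker_noise_std_m`` added to every marker coordinate.  All
    randomness derives from ``config.seed``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    axis_map = AxisMap()
    markers: dict[str, np.ndarray] = {}
    fz: dict[str, np.ndarray] = {}
    truth_events: list[GaitEvent] = []

    for lateral, side in zip((0.1, -0.1), config.sides):
        omega, _ = generate_velocity_waveform(config, side)
        omega_pre = _precompensate(omega, config.fs_markers)
        t = np.arange(len(omega)) / config.fs_markers
        theta = np.pi / 2 + cumulative_trapezoid(omega_pre, t, initial=0.0)
        phase = 2 * np.pi * (t - config.side_offset(side)) / config.stride_s
        ankle_y = 0.10 * np.sin(phase)
        ankle_z = 0.08 + 0.01 * np.sin(2 * phase)
        u_y, u_z = np.cos(theta), np.sin(theta)
        L = config.shank_length_m
        initial = side[0].upper()
        for label, r in ((f"{initial}TIB", 0.75 * L), (f"{initial}TIBI", 0.25 * L)):
            pos = np.column_stack(
                [np.full_like(t, lateral), ankle_y + r * u_y, ankle_z + r * u_z]
            )
            pos += rng.normal(0.0, config.marker_noise_std_m, pos.shape)
            markers[label] = pos
        fz[side] = _grf_series(config, side)
        hs, to = config.truth_times(side)
        for k, h in enumerate(hs):
            truth_events.append(
                GaitEvent(time_s=float(h), kind=HS, side=side, source=FORCE, cycle_index=k)
            )
        for k, tk in enumerate(to):
            truth_events.append(
                GaitEvent(time_s=float(tk), kind=TO, side=side, source=FORCE, cycle_index=k)
            )

    truth_events.sort(key=lambda e: e.time_s)
    marker_trial = MarkerTrial(
        trial_id=config.trial_id, fs=config.fs_markers, markers=markers, axis_map=axis_map
    )
    force_trial = ForceTrial(trial_id=config.trial_id, fs=config.fs_force, fz=fz)
    truth_params = params_from_events(truth_events)
    return SyntheticTrial(
        markers=marker_trial,
        force=force_trial,
        truth_events=truth_events,
        truth_params=truth_params,
        config=config,
    )
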