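"""Shank kinematics: sagittal orientation, angular velocity and filtering.

The segment orientation follows Winter's two-marker convention: with a
proximal marker at sagittal position (x1, y1) and a distal marker at
(x2, y2), the shank angle is

    theta = atan2(y1 - y2, x1 - x2)

i.e. the four-quadrant angle of the distal→proximal vector measured from
the horizontal (direction-of-progression) axis.  The angular velocity is
the time derivative of the unwrapped angle, low-pass filtered at 4 Hz with
a zero-phase 4th-order Butterworth (forward-backward) filter — the standard
treatment for 200 Hz optical marker data contaminated by soft-tissue
artifact.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, filtfilt

from .config import DetectionConfig
from .errors import DegenerateGeometryError, InsufficientDataError, ValidationError
from .types import MarkerTrial, ShankSignal

logger = logging.getLogger(__name__)

__all__ = [
    "segment_orientation",
    "angular_velocity",
    "lowpass_filter",
    "shank_signal_from_markers",
]


def segment_orientation(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Four-quadrant sagittal angle (rad) of the vector from ``p2`` to ``p1``.

    Parameters
    ----------
    p1, p2
        Sagittal-plane points ``(x, y)`` — proximal and distal marker — or
        arrays of shape (n, 2) for whole series.  ``x`` is the horizontal
        (walking-direction) coordinate, ``y`` the vertical.

    Returns
    -------
    Angle(s) in (-pi, pi].  A vertical segment with the proximal marker on
    top gives pi/2.

    Raises
    ------
    DegenerateGeometryError
        If any sample has coincident markers.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    dx = p1[..., 0] - p2[..., 0]
    dy = p1[..., 1] - p2[..., 1]
    if np.any((dx == 0) & (dy == 0)):
        raise DegenerateGeometryError("coincident markers: segment orientation undefined")
    return np.arctan2(dy, dx)


def angular_velocity(theta: np.ndarray, fs: float) -> np.ndarray:
    """Differentiate an unwrapped angle series to angular velocity (rad/s).

    Interior samples use the central difference, endpoints one-sided
    differences, so the output has the same length as the input.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size < 3:
        raise InsufficientDataError(f"need >= 3 samples to differentiate, got {theta.size}")
    if fs <= 0:
        raise ValidationError(f"fs must be > 0, got {fs}")
    return np.gradient(theta, 1.0 / fs)


def lowpass_filter(
    signal: np.ndarray, fs: float, fc: float = 4.0, order: int = 4
) -> np.ndarray:
    """Zero-phase Butterworth low-pass filter.

    The filter is applied forward and backward (``filtfilt``) so the passband
    is delayed by zero samples; the effective attenuation order is twice the
    design order.  Reflective (odd) padding handles the warm-up region.

    Raises
    ------
    ValidationError
        If ``fc >= fs / 2`` (cutoff at or above Nyquist).
    """
    signal = np.asarray(signal, dtype=float)
    if fc >= fs / 2:
        raise ValidationError(f"cutoff {fc} Hz must be below Nyquist {fs / 2} Hz")
    if fc <= 0:
        raise ValidationError(f"cutoff must be > 0, got {fc}")
    b, a = butter(order, fc, btype="low", fs=fs)
    padlen = min(signal.size - 1, 3 * max(len(a), len(b)) * 10)
    return filtfilt(b, a, signal, padlen=padlen)


def shank_signal_from_markers(
    trial: MarkerTrial,
    side: str,
    config: DetectionConfig | None = None,
) -> ShankSignal:
    """Compute the filtered shank angular velocity for one leg of a trial.

    Pipeline: project the side's proximal/distal tibia markers to the
    sagittal plane → four-quadrant orientation → unwrap → central-difference
    differentiation → 4 Hz zero-phase low-pass.  When ``auto_orient`` is on
    and the dominant velocity peaks point downward (a lab frame mirrored
    relative to the assumed convention), the velocity is negated so midswing
    is a positive peak, and the flip is logged.

    Raises
    ------
    ValidationError
        If a required tibia marker label is absent (the message names it).
    """
    config = config or DetectionConfig()
    proximal, distal = config.marker_pair(side)
    for label in (proximal, distal):
        if label not in trial.markers:
            raise ValidationError(
                f"marker {label!r} required for side {side!r} not in trial "
                f"(available: {sorted(trial.markers)})"
            )
    p1 = trial.axis_map.sagittal(trial.markers[proximal])
    p2 = trial.axis_map.sagittal(trial.markers[distal])
    if np.any(~np.isfinite(p1)) or np.any(~np.isfinite(p2)):
        raise ValidationError(
            f"markers {proximal!r}/{distal!r} contain unfilled gaps (NaN); "
            "interpolate or trim before computing kinematics"
        )
    theta = np.unwrap(segment_orientation(p1, p2))
    omega_raw = angular_velocity(theta, trial.fs)
    omega = lowpass_filter(omega_raw, trial.fs, config.cutoff_hz, config.filter_order)
    if config.auto_orient:
        # robust sign check on the signal core: filter edge transients must
        # not decide the orientation
        trim = min(len(omega) // 4, int(trial.fs))
        core = omega[trim:-trim] if len(omega) > 3 * trim else omega
        hi = float(np.quantile(core, 0.999))
        lo = float(np.quantile(core, 0.001))
        if abs(lo) > abs(hi):
            logger.info(
                "auto-orient: dominant velocity peak negative on side %r; negating", side
            )
            omega = -omega
            omega_raw = -omega_raw
    return ShankSignal(
        side=side,
        fs=trial.fs,
        theta=theta,
        omega_raw=omega_raw,
        omega=omega,
        proximal_label=proximal,
        distal_label=distal,
    )
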