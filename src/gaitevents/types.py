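"""Core domain types: trials, signals, events, cycles and parameters.

All positions are metres, times seconds, angles radians and angular
velocities rad/s unless a field name says otherwise (``*_ms`` fields are
milliseconds).  Sides are free strings; by convention ``"left"``/``"right"``
for able-bodied data and ``"sound"``/``"prosthetic"`` for amputee data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .errors import ValidationError

#: event kinds
MS, TO, HS, ZC = "MS", "TO", "HS", "ZC"
EVENT_KINDS = (MS, TO, HS, ZC)

#: event sources
KINEMATIC, FORCE = "kinematic", "force"


@dataclass(frozen=True)
class AxisMap:
    """Lab-frame convention mapping axes to anatomical directions.

    Optical mocap labs differ in which axis points up and which along the
    direction of progression; the sagittal plane used for shank orientation
    is (forward, vertical).  Defaults: vertical = Z, forward = Y.
    """

    vertical: str = "z"
    forward: str = "y"

    _IDX = {"x": 0, "y": 1, "z": 2}

    def __post_init__(self) -> None:
        v, f = self.vertical.lower(), self.forward.lower()
        if v not in self._IDX or f not in self._IDX or v == f:
            raise ValidationError(
                f"axis map must name two distinct axes from x/y/z, "
                f"got vertical={self.vertical!r} forward={self.forward!r}"
            )
        object.__setattr__(self, "vertical", v)
        object.__setattr__(self, "forward", f)

    def sagittal(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) lab-frame points to (n, 2) sagittal (forward, vertical)."""
        points = np.asarray(points, dtype=float)
        return points[..., [self._IDX[self.forward], self._IDX[self.vertical]]]


@dataclass
class MarkerTrial:
    """Time-indexed labelled 3-D marker positions at a common sampling rate.

    ``markers`` maps a label such as ``"LTIB"`` to an (n_samples, 3) array of
    positions in metres; NaN marks a gap.
    """

    trial_id: str
    fs: float
    markers: Mapping[str, np.ndarray]
    axis_map: AxisMap = field(default_factory=AxisMap)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if not self.markers:
            raise ValidationError("trial has no markers")
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        lengths = {v.shape[0] for v in self.markers.values()}
        if len(lengths) != 1:
            raise ValidationError(f"marker series lengths differ: {sorted(lengths)}")
        for label, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValidationError(f"marker {label!r} is not an (n, 3) array")

    @property
    def n_samples(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class ForceTrial:
    """Per-side vertical ground-reaction-force series in newtons."""

    trial_id: str
    fs: float
    fz: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        self.fz = {k: np.asarray(v, dtype=float) for k, v in self.fz.items()}
        for side, arr in self.fz.items():
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"force series for side {side!r} is not finite")

    def time(self, side: str) -> np.ndarray:
        return np.arange(len(self.fz[side])) / self.fs


@dataclass
class ShankSignal:
    """Sagittal shank orientation and angular velocity for one leg.

    ``theta`` is the unwrapped four-quadrant orientation of the proximal→
    distal tibia marker pair; ``omega_raw`` its time derivative and ``omega``
    the low-pass-filtered velocity the detector runs on.
    """

    side: str
    fs: float
    theta: np.ndarray
    omega_raw: np.ndarray
    omega: np.ndarray
    proximal_label: str = ""
    distal_label: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        n = len(self.theta)
        if len(self.omega_raw) != n or len(self.omega) != n:
            raise ValidationError("theta/omega_raw/omega lengths differ")
        if not np.all(np.isfinite(self.omega)):
            raise ValidationError("filtered omega contains non-finite samples")

    def time(self) -> np.ndarray:
        return np.arange(len(self.theta)) / self.fs


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A timestamped gait landmark.

    ``kind`` is one of MS (midswing velocity peak), TO (toe-off), HS (heel
    strike) or ZC (negative-to-positive zero crossing); ``source`` records
    whether the event came from shank kinematics or from force-plate data.
    """

    time_s: float
    kind: str
    side: str
    source: str = KINEMATIC
    cycle_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.source not in (KINEMATIC, FORCE):
            raise ValidationError(f"unknown event source {self.source!r}")
        if not np.isfinite(self.time_s) or self.time_s < 0:
            raise ValidationError(f"event time must be finite and >= 0, got {self.time_s}")


@dataclass(frozen=True)
class GaitCycle:
    """One complete gait cycle: same-side HS to HS with one TO in between."""

    side: str
    cycle_index: int
    hs_start: float
    to: float
    hs_end: float
    contralateral_hs: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hs_start < self.to < self.hs_end:
            raise ValidationError(
                f"cycle ordering violated: HS {self.hs_start} < TO {self.to} "
                f"< HS {self.hs_end} must hold"
            )


@dataclass(frozen=True)
class TemporalParams:
    """Per-cycle temporal gait parameters in seconds.

    ``swing_time`` is defined as ``stride_time - stance_time`` so the
    stance + swing = stride identity holds bit-exactly.
    """

    side: str
    cycle_index: int
    stride_time: float
    stance_time: float
    swing_time: float
    step_time: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("stride_time", "stance_time", "swing_time"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.step_time is not None and self.step_time <= 0:
            raise ValidationError("step_time must be > 0 when present")
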