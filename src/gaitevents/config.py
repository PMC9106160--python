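"""Detection configuration.

All knobs of the pipeline live here so the CLI, the library and the tests
share one source of defaults.  Values can be overridden from a YAML mapping
with the same key names.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError


@dataclass
class DetectionConfig:
    """Tunable parameters of the event-detection pipeline.

    Attributes
    ----------
    cutoff_hz
        Low-pass cutoff for the angular-velocity signal (Hz).  4 Hz keeps
        the gait band intact while suppressing soft-tissue artifact.
    filter_order
        Butterworth design order; applied forward-backward.
    auto_orient
        Negate the velocity when its dominant peaks are negative, so that
        midswing is always a positive peak regardless of lab frame.
    peak_frac
        A positive local maximum qualifies as a midswing peak when its
        height is at least ``peak_frac`` times the median positive-maximum
        height — a relative criterion, robust across walking speeds.
    min_cycle_s
        Minimum separation between consecutive midswing peaks (s); 0.4 s
        corresponds to a maximum cadence of 150 strides/min.
    grf_threshold_n
        Vertical-force threshold (N) separating stance from swing for
        reference events; 20 N is the common treadmill convention.
    debounce_s
        Threshold crossings closer together than this (s) are treated as
        chatter and merged.
    proximal_markers / distal_markers
        Per-side tibia marker labels; ``{S}`` expands to the side's initial
        in upper case (left→L, right→R), matching the LTIB/LTIBI/RTIB/RTIBI
        labelling of treadmill mocap data sets.
    """

    cutoff_hz: float = 4.0
    filter_order: int = 4
    auto_orient: bool = True
    peak_frac: float = 0.5
    min_cycle_s: float = 0.4
    grf_threshold_n: float = 20.0
    debounce_s: float = 0.05
    proximal_markers: Mapping[str, str] = field(default_factory=dict)
    distal_markers: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ConfigError(f"cutoff_hz must be > 0, got {self.cutoff_hz}")
        if self.filter_order < 1:
            raise ConfigError(f"filter_order must be >= 1, got {self.filter_order}")
        if not 0 < self.peak_frac:
            raise ConfigError(f"peak_frac must be > 0, got {self.peak_frac}")
        if self.min_cycle_s <= 0:
            raise ConfigError(f"min_cycle_s must be > 0, got {self.min_cycle_s}")
        if self.debounce_s < 0:
            raise ConfigError(f"debounce_s must be >= 0, got {self.debounce_s}")

    def marker_pair(self, side: str) -> tuple[str, str]:
        """Proximal and distal tibia marker labels for ``side``.

        Defaults to ``<S>TIB`` (proximal) and ``<S>TIBI`` (inferior tibia,
        distal) where ``<S>`` is the side's initial in upper case.
        """
        initial = side[0].upper()
        proximal = self.proximal_markers.get(side, f"{initial}TIB")
        distal = self.distal_markers.get(side, f"{initial}TIBI")
        return proximal, distal

    @classmethod
    def from_dict(cls, data: Mapping) -> "DetectionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DetectionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
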