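"""High-level pipeline: markers → events → parameters → validation report.

Composes the kinematics, detection, segmentation and validation layers the
way a user of the tool runs them end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import DetectionConfig
from .cycles import build_cycles, compute_params
from .errors import ValidationError
from .events import detect_events, grf_reference_events
from .kinematics import shank_signal_from_markers
from .types import HS, TO, ForceTrial, GaitEvent, MarkerTrial, TemporalParams
from .validation import (
    AgreementStats,
    ErrorSummary,
    EventError,
    bland_altman,
    event_errors,
    match_events,
    normalize_errors,
    summarize_errors,
)

__all__ = ["detect_trial", "reference_events", "compare_to_reference", "ValidationReport"]

PARAMETERS = ("step", "stride", "stance", "swing")


def detect_trial(
    markers: MarkerTrial,
    sides: Sequence[str] | None = None,
    config: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """Detect kinematic MS/TO/HS events for the given sides of a trial.

    Sides default to those whose tibia marker pairs are present, inferred
    from the labels (e.g. LTIB/LTIBI → "left").
    """
    config = config or DetectionConfig()
    if sides is None:
        sides = _infer_sides(markers, config)
    events: list[GaitEvent] = []
    for side in sides:
        signal = shank_signal_from_markers(markers, side, config)
        events.extend(detect_events(signal, config))
    events.sort(key=lambda e: e.time_s)
    return events


_SIDE_BY_INITIAL = {"L": "left", "R": "right", "S": "sound", "P": "prosthetic"}


def _infer_sides(markers: MarkerTrial, config: DetectionConfig) -> list[str]:
    sides = []
    for initial, side in _SIDE_BY_INITIAL.items():
        proximal, distal = config.marker_pair(side)
        if proximal in markers.markers and distal in markers.markers:
            sides.append(side)
    if not sides:
        raise ValidationError(
            f"no side with a complete tibia marker pair; labels: {sorted(markers.markers)}"
        )
    return sides


def reference_events(
    force: ForceTrial,
    sides: Sequence[str] | None = None,
    config: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """Force-threshold HS/TO reference events for every (or given) side."""
    config = config or DetectionConfig()
    sides = list(sides) if sides is not None else sorted(force.fz)
    events: list[GaitEvent] = []
    for side in sides:
        events.extend(grf_reference_events(force, side, config))
    events.sort(key=lambda e: e.time_s)
    return events


@dataclass
class ValidationReport:
    """Outcome of comparing detected events against a reference.

    ``errors`` carries per-event signed timing errors (stride-normalised),
    ``summaries`` the per-(kind, side) ME/MAE/SD, and ``agreement`` the
    Bland-Altman statistics for each temporal parameter computed from both
    event streams over paired cycles.
    """

    errors: list[EventError]
    summaries: list[ErrorSummary]
    agreement: Mapping[str, AgreementStats]
    n_unmatched_predicted: int = 0
    n_unmatched_reference: int = 0
    predicted_params: list[TemporalParams] = field(default_factory=list)
    reference_params: list[TemporalParams] = field(default_factory=list)

    def summary(self, kind: str, side: str) -> ErrorSummary:
        for s in self.summaries:
            if s.kind == kind and s.side == side:
                return s
        raise KeyError(f"no summary for kind={kind!r} side={side!r}")


def compare_to_reference(
    predicted: Sequence[GaitEvent],
    reference: Sequence[GaitEvent],
    config: DetectionConfig | None = None,
) -> ValidationReport:
    """Match predicted TO/HS events to reference events and summarize.

    Event errors use the sign convention that early prediction is positive.
    Temporal-parameter agreement pairs complete cycles built independently
    from the predicted and reference event streams (cycles paired by nearest
    heel-strike within half a stride) and reports Bland-Altman statistics
    per parameter.
    """
    errors: list[EventError] = []
    n_up = n_ur = 0
    kinds = sorted({(e.kind, e.side) for e in reference if e.kind in (TO, HS)})
    for kind, side in kinds:
        pred = [e for e in predicted if e.kind == kind and e.side == side]
        ref = [e for e in reference if e.kind == kind and e.side == side]
        result = match_events(pred, ref)
        errors.extend(event_errors(result.pairs))
        n_up += len(result.unmatched_predicted)
        n_ur += len(result.unmatched_reference)
    errors = normalize_errors(errors)
    summaries = summarize_errors(errors)

    pred_cycles = build_cycles([e for e in predicted if e.kind in (TO, HS)])
    ref_cycles = build_cycles([e for e in reference if e.kind in (TO, HS)])
    pred_params, ref_params, agreement = _paired_agreement(pred_cycles, ref_cycles)
    return ValidationReport(
        errors=errors,
        summaries=summaries,
        agreement=agreement,
        n_unmatched_predicted=n_up,
        n_unmatched_reference=n_ur,
        predicted_params=pred_params,
        reference_params=ref_params,
    )


def _paired_agreement(pred_cycles, ref_cycles):
    pairs = []
    used = set()
    for rc in ref_cycles:
        stride = rc.hs_end - rc.hs_start
        best = None
        for i, pc in enumerate(pred_cycles):
            if i in used or pc.side != rc.side:
                continue
            gap = abs(pc.hs_start - rc.hs_start)
            if gap <= stride / 2 and (best is None or gap < best[0]):
                best = (gap, i)
        if best is not None:
            used.add(best[1])
            pairs.append((pred_cycles[best[1]], rc))
    pred_params = [compute_params(pc) for pc, _ in pairs]
    ref_params = [compute_params(rc) for _, rc in pairs]
    agreement = {}
    for name in PARAMETERS:
        attr = f"{name}_time"
        m = [getattr(p, attr) for p in pred_params]
        r = [getattr(p, attr) for p in ref_params]
        paired = [(a, b) for a, b in zip(m, r) if a is not None and b is not None]
        if len(paired) >= 2:
            mm, rr = zip(*paired)
            agreement[name] = bland_altman(np.array(mm), np.array(rr), parameter=name)
    return pred_params, ref_params, agreement
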