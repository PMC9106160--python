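"""The dual-minima gait event detector.

The algorithm anchors on the dominant positive peak of the filtered shank
sagittal angular velocity in each gait cycle — midswing (MS), when the shank
swings fastest forward.  Each MS peak is flanked by two negative minima
marking the reversals of shank rotation: the minimum *before* MS is taken as
toe-off (TO) and the minimum *after* as heel strike (HS).  A negative-to-
positive zero crossing (ZC) after TO bounds the "NP-ZC zone" in which the
true toe-off is expected to fall.

Reference events for validation come from thresholding the vertical ground
reaction force: an upward crossing of the threshold is a heel strike, a
downward crossing a toe-off.
"""
from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .config import DetectionConfig
from .errors import ValidationError
from .types import FORCE, HS, KINEMATIC, MS, TO, ZC, ForceTrial, GaitEvent, ShankSignal

logger = logging.getLogger(__name__)

__all__ = [
    "detect_midswing",
    "detect_to_hs",
    "detect_events",
    "zero_crossing_to",
    "grf_reference_events",
]


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; plateaus resolve to their left edge."""
    _, props = find_peaks(x, plateau_size=1)
    return props["left_edges"].astype(int)


def detect_midswing(
    omega: np.ndarray,
    fs: float,
    side: str = "",
    config: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """Detect midswing events: the largest positive peaks of the velocity.

    A positive local maximum qualifies when its height is at least
    ``peak_frac`` times the median height of all positive local maxima
    (so the criterion is invariant to uniform scaling of the signal), and
    qualifying peaks closer together than ``min_cycle_s`` are thinned
    keeping the higher peak.

    Returns an empty list when no peak qualifies; raises on NaNs.
    """
    config = config or DetectionConfig()
    omega = np.asarray(omega, dtype=float)
    if np.any(np.isnan(omega)):
        raise ValidationError("omega contains NaNs")
    if fs <= 0:
        raise ValidationError(f"fs must be > 0, got {fs}")
    maxima = _local_maxima(omega)
    maxima = maxima[omega[maxima] > 0]
    if maxima.size == 0:
        return []
    # relative height criterion over the dominant-peak class: small positive
    # stance ripples would otherwise drag the median down and qualify
    heights = omega[maxima]
    dominant = heights[heights >= 0.5 * heights.max()]
    threshold = config.peak_frac * float(np.median(dominant))
    candidates = maxima[heights >= threshold]
    # thin by min_cycle_s keeping the higher of any close pair
    min_dist = max(1, int(round(config.min_cycle_s * fs)))
    keep: list[int] = []
    for idx in candidates[np.argsort(omega[candidates])[::-1]]:  # tallest first
        if all(abs(idx - k) >= min_dist for k in keep):
            keep.append(int(idx))
    keep.sort()
    return [
        GaitEvent(time_s=i / fs, kind=MS, side=side, source=KINEMATIC, cycle_index=c)
        for c, i in enumerate(keep)
    ]


def _negative_minima(omega: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Indices of negative-valued local minima of omega within [lo, hi)."""
    if hi - lo < 3:
        return np.array([], dtype=int)
    window = omega[lo:hi]
    _, props = find_peaks(-window, plateau_size=1)
    idx = props["left_edges"].astype(int) + lo
    return idx[omega[idx] < 0]


def detect_to_hs(
    omega: np.ndarray,
    fs: float,
    ms_events: Sequence[GaitEvent],
    config: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """Assign the flanking negative minima of each MS peak as TO and HS.

    For MS peak *k* the toe-off is the nearest negative local minimum
    before it (searched back to the previous MS) and the heel strike the
    nearest negative local minimum after it (searched up to the next MS).
    A "negative peak" requires the velocity to actually be negative at the
    minimum; non-negative local minima are not events.  An MS at a trial
    boundary missing a flank produces no event for that flank (the cycle is
    incomplete, which is logged).  If a single negative minimum separates
    two MS peaks it serves as HS of the earlier cycle *and* TO of the later
    one, with a warning — a pathological waveform worth the operator's eye.
    """
    omega = np.asarray(omega, dtype=float)
    times = [ev.time_s for ev in ms_events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("ms_events must be strictly increasing in time")
    ms_idx = [int(round(ev.time_s * fs)) for ev in ms_events]
    events: list[GaitEvent] = []
    after_prev: Optional[int] = None
    for k, (ev, m) in enumerate(zip(ms_events, ms_idx)):
        lo = ms_idx[k - 1] if k > 0 else 0
        hi = ms_idx[k + 1] if k + 1 < len(ms_idx) else len(omega)
        before = _negative_minima(omega, lo, m)
        after = _negative_minima(omega, m, hi)
        if before.size:
            events.append(
                GaitEvent(time_s=int(before[-1]) / fs, kind=TO, side=ev.side,
                          source=KINEMATIC, cycle_index=ev.cycle_index)
            )
            if k > 0 and after_prev is not None and int(before[-1]) == after_prev:
                logger.warning(
                    "single negative minimum between MS peaks %d and %d shared "
                    "as HS and TO", k - 1, k,
                )
        else:
            logger.info("MS peak %d has no preceding negative minimum; cycle incomplete", k)
        if after.size:
            events.append(
                GaitEvent(time_s=int(after[0]) / fs, kind=HS, side=ev.side,
                          source=KINEMATIC, cycle_index=ev.cycle_index)
            )
            after_prev = int(after[0])
        else:
            logger.info("MS peak %d has no following negative minimum; cycle incomplete", k)
            after_prev = None
    events.sort(key=lambda e: e.time_s)
    return events


def detect_events(
    signal: ShankSignal, config: DetectionConfig | None = None
) -> list[GaitEvent]:
    """Run the full dual-minima detection on a shank signal.

    Returns the MS, TO and HS events sorted by time.
    """
    config = config or DetectionConfig()
    ms = detect_midswing(signal.omega, signal.fs, signal.side, config)
    to_hs = detect_to_hs(signal.omega, signal.fs, ms, config)
    return sorted(ms + to_hs, key=lambda e: e.time_s)


def zero_crossing_to(
    omega: np.ndarray,
    fs: float,
    to_event: GaitEvent,
    until_s: float | None = None,
) -> Optional[GaitEvent]:
    """The first negative→positive crossing of the velocity after a TO event.

    The crossing time is linearly interpolated between the bracketing
    samples; together with the TO it bounds the NP-ZC zone expected to
    contain the true toe-off.  Returns ``None`` (logged) when no crossing
    occurs before ``until_s`` (typically the next MS peak).
    """
    if to_event.kind != TO or to_event.source != KINEMATIC:
        raise ValidationError("zero_crossing_to expects a kinematic TO event")
    omega = np.asarray(omega, dtype=float)
    start = int(round(to_event.time_s * fs))
    stop = len(omega) - 1 if until_s is None else min(len(omega) - 1, int(round(until_s * fs)))
    for i in range(start, stop):
        if omega[i] < 0 <= omega[i + 1]:
            frac = -omega[i] / (omega[i + 1] - omega[i])
            t = (i + frac) / fs
            return GaitEvent(time_s=t, kind=ZC, side=to_event.side,
                             source=KINEMATIC, cycle_index=to_event.cycle_index)
        if omega[i] >= 0:
            # already positive right after TO: the crossing sits at this sample
            return GaitEvent(time_s=i / fs, kind=ZC, side=to_event.side,
                             source=KINEMATIC, cycle_index=to_event.cycle_index)
    logger.info("no zero crossing after TO at %.3f s before %.3f s", to_event.time_s, (stop / fs))
    return None


def grf_reference_events(
    force: ForceTrial,
    side: str,
    config: DetectionConfig | None = None,
) -> list[GaitEvent]:
    """Reference HS/TO events from a threshold on the vertical GRF.

    An upward crossing of ``grf_threshold_n`` marks heel strike, a downward
    crossing toe-off; crossing times are interpolated between the bracketing
    force samples.  Contact or swing intervals shorter than ``debounce_s``
    are treated as chatter and merged.  Events alternate HS, TO, HS, ...
    """
    config = config or DetectionConfig()
    if side not in force.fz:
        raise ValidationError(
            f"no vertical force for side {side!r} (available: {sorted(force.fz)})"
        )
    fz = np.asarray(force.fz[side], dtype=float)
    fs = force.fs
    thr = config.grf_threshold_n
    above = fz >= thr
    changes = np.flatnonzero(np.diff(above.astype(int)))  # crossing between i and i+1
    crossings = []  # (time, kind)
    for i in changes:
        frac = (thr - fz[i]) / (fz[i + 1] - fz[i])
        t = (i + frac) / fs
        crossings.append((t, HS if above[i + 1] else TO))
    # debounce: drop crossing pairs bounding an interval shorter than debounce_s
    filtered: list[tuple[float, str]] = []
    for c in crossings:
        if filtered and c[0] - filtered[-1][0] < config.debounce_s:
            filtered.pop()  # the short blip and its opener cancel
        else:
            filtered.append(c)
    # enforce alternation starting at HS
    events: list[GaitEvent] = []
    expect = HS
    for t, kind in filtered:
        if kind != expect:
            logger.warning("dropping non-alternating %s crossing at %.3f s", kind, t)
            continue
        events.append(GaitEvent(time_s=t, kind=kind, side=side, source=FORCE))
        expect = TO if kind == HS else HS
    return events
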