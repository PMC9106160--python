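"""Segmentation of gait events into complete cycles and temporal parameters.

A complete gait cycle is defined HS→HS for the same leg; the half-cycles at
the start and end of a trial are discarded.  Each cycle yields four temporal
parameters: stride time (HS to next ipsilateral HS), stance time (HS to TO),
swing time (the remainder of the stride) and step time (HS to the next
contralateral HS).  Events of different sources (kinematic vs force) are
never mixed within one cycle: segment each source's event list separately.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .errors import ValidationError
from .types import HS, TO, GaitCycle, GaitEvent, TemporalParams

logger = logging.getLogger(__name__)

__all__ = ["build_cycles", "compute_params", "params_from_events"]


def build_cycles(events: Iterable[GaitEvent]) -> list[GaitCycle]:
    """Build complete gait cycles from a pool of HS/TO events (both sides).

    For each side, every pair of consecutive heel strikes containing exactly
    one toe-off between them becomes a cycle; pairs with zero or multiple
    TOs are rejected and logged (spurious or missed events).  The
    contralateral heel strike attached to a cycle is the first opposite-side
    HS in ``(hs_start, hs_end]``.  Mixed-source event pools are rejected.
    """
    events = sorted(events, key=lambda e: e.time_s)
    sources = {e.source for e in events}
    if len(sources) > 1:
        raise ValidationError(f"events mix sources {sorted(sources)}; segment per source")
    sides = sorted({e.side for e in events})
    hs_by_side = {s: [e.time_s for e in events if e.side == s and e.kind == HS] for s in sides}
    to_by_side = {s: [e.time_s for e in events if e.side == s and e.kind == TO] for s in sides}
    cycles: list[GaitCycle] = []
    for side in sides:
        hs = hs_by_side[side]
        tos = to_by_side[side]
        other_hs = [t for s in sides if s != side for t in hs_by_side[s]]
        other_hs.sort()
        index = 0
        for start, end in zip(hs, hs[1:]):
            inside = [t for t in tos if start < t < end]
            if len(inside) != 1:
                logger.warning(
                    "side %r HS pair (%.3f, %.3f) contains %d TO events; cycle rejected",
                    side, start, end, len(inside),
                )
                continue
            contra = next((t for t in other_hs if start < t <= end), None)
            cycles.append(
                GaitCycle(side=side, cycle_index=index, hs_start=start,
                          to=inside[0], hs_end=end, contralateral_hs=contra)
            )
            index += 1
    if not cycles:
        logger.warning("no complete gait cycles found")
    cycles.sort(key=lambda c: (c.hs_start, c.side))
    return cycles


def compute_params(cycle: GaitCycle) -> TemporalParams:
    """Temporal parameters of one cycle.

    stride = hs_end - hs_start; stance = to - hs_start; swing is computed as
    stride - stance so that stance + swing reproduces stride bit-exactly;
    step = contralateral_hs - hs_start, absent when no contralateral HS fell
    inside the cycle.
    """
    stride = cycle.hs_end - cycle.hs_start
    stance = cycle.to - cycle.hs_start
    swing = stride - stance
    step = None if cycle.contralateral_hs is None else cycle.contralateral_hs - cycle.hs_start
    return TemporalParams(
        side=cycle.side,
        cycle_index=cycle.cycle_index,
        stride_time=stride,
        stance_time=stance,
        swing_time=swing,
        step_time=step,
    )


def params_from_events(events: Iterable[GaitEvent]) -> list[TemporalParams]:
    """Convenience: segment events into cycles and compute all parameters."""
    return [compute_params(c) for c in build_cycles(events)]
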