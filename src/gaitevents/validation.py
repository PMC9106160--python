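"""Validation of detected events against force-plate reference events.

Signed timing errors follow the convention that an error is *positive when
the predicted event precedes the actual (reference) event*:

    e = (t_reference - t_predicted) * 1000  [ms]

Summaries report the mean signed error (ME), mean absolute error (MAE) and
sample standard deviation per group, optionally normalised by the local
reference stride duration for comparison across walking speeds.  Agreement
between method- and reference-derived temporal parameters uses Bland-Altman
statistics: bias (mean difference), limits of agreement bias ± 1.96·SD, the
reproducibility coefficient RPC = 1.96·SD, and a percent coefficient of
variation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .types import GaitEvent

logger = logging.getLogger(__name__)

__all__ = [
    "EventError",
    "ErrorSummary",
    "AgreementStats",
    "MatchResult",
    "match_events",
    "event_errors",
    "summarize_errors",
    "normalize_errors",
    "bland_altman",
]


@dataclass(frozen=True)
class EventError:
    """Signed timing error of one predicted event vs its reference.

    ``e_ms`` is positive when the prediction precedes the reference;
    ``stride_s`` is the enclosing reference stride duration and ``e_pct``
    the stride-normalised absolute error, filled by :func:`normalize_errors`.
    """

    kind: str
    side: str
    e_ms: float
    stride_s: Optional[float] = None
    e_pct: Optional[float] = None


@dataclass(frozen=True)
class ErrorSummary:
    """ME/MAE/SD of a group of event errors (milliseconds)."""

    kind: str
    side: str
    n: int
    me_ms: float
    mae_ms: float
    sd_ms: Optional[float]


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between two measurements of one parameter.

    Differences are method − reference; ``rpc`` = 1.96·SD of differences,
    limits of agreement = bias ∓/± rpc, ``cv`` = 100·SD / grand mean of the
    pairwise means.
    """

    parameter: str
    n: int
    bias: float
    sd: float
    rpc: float
    loa_low: float
    loa_high: float
    cv: float


@dataclass
class MatchResult:
    """One-to-one pairing of predicted with reference events."""

    pairs: list[tuple[GaitEvent, GaitEvent]]
    unmatched_predicted: list[GaitEvent]
    unmatched_reference: list[GaitEvent]


def _local_strides(times: Sequence[float]) -> list[float]:
    """Local stride duration around each reference event of one kind/side.

    For interior events: half the distance between the two neighbours; at
    the ends: the single adjacent gap.  With fewer than two events the
    stride is unknown (NaN).
    """
    n = len(times)
    if n < 2:
        return [float("nan")] * n
    strides = []
    for j in range(n):
        lo = times[j - 1] if j > 0 else None
        hi = times[j + 1] if j + 1 < n else None
        if lo is not None and hi is not None:
            strides.append((hi - lo) / 2)
        elif hi is not None:
            strides.append(hi - times[j])
        else:
            strides.append(times[j] - lo)
    return strides


def match_events(
    predicted: Sequence[GaitEvent], reference: Sequence[GaitEvent]
) -> MatchResult:
    """Pair predicted events with reference events of the same kind and side.

    Greedy one-to-one nearest-neighbour matching: candidate pairs within
    half the local reference stride are taken in order of increasing time
    gap.  Events left over on either side are reported unmatched.
    """
    kinds = {(e.kind, e.side) for e in predicted} | {(e.kind, e.side) for e in reference}
    if len(kinds) > 1:
        raise ValidationError(
            f"match_events expects one (kind, side) group, got {sorted(kinds)}"
        )
    pred = sorted(predicted, key=lambda e: e.time_s)
    ref = sorted(reference, key=lambda e: e.time_s)
    ref_times = [e.time_s for e in ref]
    windows = [s / 2 for s in _local_strides(ref_times)]
    candidates = []
    for i, p in enumerate(pred):
        for j, r in enumerate(ref):
            gap = abs(p.time_s - r.time_s)
            w = windows[j]
            if np.isnan(w) or gap <= w:
                candidates.append((gap, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[GaitEvent, GaitEvent]] = []
    for _, i, j in candidates:
        if i in used_p or j in used_r:
            continue
        used_p.add(i)
        used_r.add(j)
        pairs.append((pred[i], ref[j]))
    pairs.sort(key=lambda pr: pr[1].time_s)
    return MatchResult(
        pairs=pairs,
        unmatched_predicted=[p for i, p in enumerate(pred) if i not in used_p],
        unmatched_reference=[r for j, r in enumerate(ref) if j not in used_r],
    )


def event_errors(
    pairs: Sequence[tuple[GaitEvent, GaitEvent]]
) -> list[EventError]:
    """Signed errors (ms) of matched pairs; early prediction ⇒ positive."""
    ref_times = [r.time_s for _, r in pairs]
    strides = _local_strides(ref_times)
    errors = []
    for (p, r), stride in zip(pairs, strides):
        errors.append(
            EventError(
                kind=r.kind,
                side=r.side,
                e_ms=(r.time_s - p.time_s) * 1000.0,
                stride_s=None if np.isnan(stride) else stride,
            )
        )
    return errors


def summarize_errors(
    errors: Sequence[EventError], group_by: Sequence[str] = ("kind", "side")
) -> list[ErrorSummary]:
    """Per-group ME, MAE and sample SD (n−1) of signed errors.

    Groups with a single error report SD as unavailable (None); empty
    inputs produce an empty list.
    """
    if not errors:
        logger.warning("no errors to summarize")
        return []
    frame = pd.DataFrame(
        {"kind": [e.kind for e in errors], "side": [e.side for e in errors],
         "e_ms": [e.e_ms for e in errors]}
    )
    out = []
    for key, grp in frame.groupby(list(group_by), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        labels = dict(zip(group_by, key))
        e = grp["e_ms"].to_numpy()
        out.append(
            ErrorSummary(
                kind=labels.get("kind", "*"),
                side=labels.get("side", "*"),
                n=len(e),
                me_ms=float(np.mean(e)),
                mae_ms=float(np.mean(np.abs(e))),
                sd_ms=float(np.std(e, ddof=1)) if len(e) > 1 else None,
            )
        )
    return out


def normalize_errors(errors: Sequence[EventError]) -> list[EventError]:
    """Fill ``e_pct`` = 100·|e_ms| / (1000·stride_s) for each error.

    Errors with no stride duration are returned unnormalised and logged.
    """
    out = []
    for e in errors:
        if e.stride_s is None or not e.stride_s > 0:
            logger.warning("error of kind %s has no stride duration; left unnormalized", e.kind)
            out.append(e)
        else:
            out.append(replace(e, e_pct=100.0 * abs(e.e_ms) / (1000.0 * e.stride_s)))
    return out


def bland_altman(
    method_values: Sequence[float],
    reference_values: Sequence[float],
    parameter: str = "",
) -> AgreementStats:
    """Bland-Altman agreement statistics for paired measurements.

    Differences are method − reference, so a method that under-estimates
    the parameter shows a negative bias.
    """
    m = np.asarray(method_values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if m.shape != r.shape:
        raise ValidationError(f"paired series differ in length: {m.shape} vs {r.shape}")
    if m.size < 2:
        raise InsufficientDataError(f"need >= 2 pairs for agreement, got {m.size}")
    d = m - r
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    rpc = 1.96 * sd
    grand_mean = float(np.mean((m + r) / 2))
    cv = 100.0 * sd / grand_mean if grand_mean != 0 else float("nan")
    return AgreementStats(
        parameter=parameter,
        n=int(m.size),
        bias=bias,
        sd=sd,
        rpc=rpc,
        loa_low=bias - rpc,
        loa_high=bias + rpc,
        cv=cv,
    )
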