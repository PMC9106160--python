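"""Reading and writing marker, force, event and parameter tables.

The CSV marker dialect: an optional first column ``time_s``, then one column
triple per marker named ``<LABEL>_X``, ``<LABEL>_Y``, ``<LABEL>_Z`` (metres);
decimal point, comma separator, UTF-8.  Gaps are empty cells or NaN.  C3D
reading is available when the optional ``ezc3d`` dependency is installed.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError
from .types import AxisMap, ForceTrial, GaitEvent, MarkerTrial, TemporalParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_marker_csv",
    "write_marker_csv",
    "read_force_csv",
    "write_force_csv",
    "read_c3d",
    "write_events",
    "read_events",
    "write_params",
    "read_params",
    "fill_gaps",
]

_TIBIA_LABELS = ("LTIB", "LTIBI", "RTIB", "RTIBI")
_MARKER_COL = re.compile(r"^(?P<label>.+)_(?P<axis>[XYZ])$")


def read_marker_csv(
    path: str | Path,
    fs: float | None = None,
    axis_map: AxisMap | None = None,
    trial_id: str | None = None,
) -> MarkerTrial:
    """Read a marker trajectory CSV into a :class:`MarkerTrial`.

    ``fs`` may be omitted when the file has a ``time_s`` column (the rate is
    then inferred from the median time step).  Unknown labels are retained;
    gaps stay NaN (see :func:`fill_gaps`).
    """
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    columns = list(frame.columns)
    if columns and columns[0] == "time_s":
        time = frame.pop("time_s").to_numpy(dtype=float)
        if len(time) > 1:
            fs_inferred = 1.0 / float(np.median(np.diff(time)))
            if fs is None:
                fs = fs_inferred
            elif abs(fs - fs_inferred) / fs > 0.01:
                raise FormatError(
                    f"{path}: time_s column implies fs≈{fs_inferred:.3f} Hz, "
                    f"conflicting with fs={fs}"
                )
    if fs is None:
        raise ValidationError(f"{path}: no time_s column; fs must be given")
    markers: dict[str, dict[str, np.ndarray]] = {}
    for col in frame.columns:
        m = _MARKER_COL.match(str(col))
        if not m:
            raise FormatError(
                f"{path}: column {col!r} does not match '<LABEL>_X|_Y|_Z'"
            )
        markers.setdefault(m["label"], {})[m["axis"]] = frame[col].to_numpy(dtype=float)
    arrays = {}
    for label, axes in markers.items():
        missing = set("XYZ") - set(axes)
        if missing:
            raise FormatError(f"{path}: marker {label!r} missing axes {sorted(missing)}")
        arrays[label] = np.column_stack([axes["X"], axes["Y"], axes["Z"]])
    return MarkerTrial(
        trial_id=trial_id or Path(path).stem,
        fs=fs,
        markers=arrays,
        axis_map=axis_map or AxisMap(),
    )


def write_marker_csv(trial: MarkerTrial, path: str | Path) -> None:
    """Write a trial in the CSV marker dialect, with a ``time_s`` column."""
    data = {"time_s": trial.time()}
    for label, arr in trial.markers.items():
        for i, axis in enumerate("XYZ"):
            data[f"{label}_{axis}"] = arr[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


def read_force_csv(path: str | Path, fs: float | None = None, trial_id: str | None = None) -> ForceTrial:
    """Read per-side vertical force from CSV columns ``Fz_<side>`` (+ optional time_s)."""
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise EmptyInputError(f"{path}: no data rows")
    if list(frame.columns)[:1] == ["time_s"]:
        time = frame.pop("time_s").to_numpy(dtype=float)
        if fs is None and len(time) > 1:
            fs = 1.0 / float(np.median(np.diff(time)))
    if fs is None:
        raise ValidationError(f"{path}: no time_s column; fs must be given")
    fz = {}
    for col in frame.columns:
        if not str(col).startswith("Fz_"):
            raise FormatError(f"{path}: column {col!r} does not match 'Fz_<side>'")
        fz[str(col)[3:]] = frame[col].to_numpy(dtype=float)
    return ForceTrial(trial_id=trial_id or Path(path).stem, fs=fs, fz=fz)


def write_force_csv(force: ForceTrial, path: str | Path) -> None:
    data = {"time_s": np.arange(max(len(v) for v in force.fz.values())) / force.fs}
    for side, arr in force.fz.items():
        data[f"Fz_{side}"] = arr
    pd.DataFrame(data).to_csv(path, index=False)


def read_c3d(path: str | Path) -> tuple[MarkerTrial, Optional[ForceTrial]]:
    """Read markers (and vertical force analogs, if any) from a C3D file.

    Requires the optional ``ezc3d`` dependency (``pip install gaitevents[c3d]``).
    Point rate becomes the marker sampling rate and analog channels whose
    label contains ``Fz`` become per-side force series.  Raises a
    :class:`FormatError` naming the available labels when none of the four
    tibia markers (LTIB/LTIBI/RTIB/RTIBI) is present.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - exercised only without ezc3d
        raise ImportError(
            "reading C3D files requires the optional dependency ezc3d; "
            "install with 'pip install gaitevents[c3d]' or export to CSV"
        ) from exc
    try:
        c3d = ezc3d.c3d(str(path))
    except Exception as exc:
        raise FormatError(f"unreadable C3D file {path}: {exc}") from exc
    labels = [str(s).strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    fs_markers = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    markers = {
        label: points[:3, i, :].T.astype(float) for i, label in enumerate(labels)
    }
    if not any(lbl in markers for lbl in _TIBIA_LABELS):
        raise FormatError(
            f"{path}: none of the tibia markers {_TIBIA_LABELS} present; "
            f"available labels: {sorted(markers)}"
        )
    force = None
    analogs = c3d["data"]["analogs"]  # (1, n_channels, n_samples)
    if analogs.size:
        analog_labels = [
            str(s).strip() for s in c3d["parameters"]["ANALOG"]["LABELS"]["value"]
        ]
        fs_force = float(c3d["parameters"]["ANALOG"]["RATE"]["value"][0])
        fz = {
            lbl: analogs[0, i, :].astype(float)
            for i, lbl in enumerate(analog_labels)
            if "fz" in lbl.lower()
        }
        if fz:
            force = ForceTrial(trial_id=Path(path).stem, fs=fs_force, fz=fz)
    return (
        MarkerTrial(trial_id=Path(path).stem, fs=fs_markers, markers=markers),
        force,
    )


def fill_gaps(trial: MarkerTrial, max_gap: int = 10) -> MarkerTrial:
    """Linearly interpolate short marker gaps (≤ ``max_gap`` samples).

    Longer gaps are left NaN — they invalidate the enclosing cycles and the
    kinematics layer refuses them — and logged.
    """
    filled = {}
    for label, arr in trial.markers.items():
        arr = arr.copy()
        nan = np.isnan(arr).any(axis=1)
        if nan.any():
            runs = _nan_runs(nan)
            idx = np.arange(len(arr))
            for start, stop in runs:
                if stop - start <= max_gap and start > 0 and stop < len(arr):
                    for j in range(3):
                        arr[start:stop, j] = np.interp(
                            idx[start:stop], [start - 1, stop], [arr[start - 1, j], arr[stop, j]]
                        )
                    logger.warning(
                        "interpolated %d-sample gap in marker %s", stop - start, label
                    )
                else:
                    logger.warning(
                        "gap of %d samples in marker %s exceeds max_gap=%d; left as NaN",
                        stop - start, label, max_gap,
                    )
        filled[label] = arr
    return MarkerTrial(
        trial_id=trial.trial_id, fs=trial.fs, markers=filled, axis_map=trial.axis_map
    )


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def write_events(events: Sequence[GaitEvent], path: str | Path, trial_id: str = "") -> None:
    """Write events to CSV (trial_id, side, kind, time_s, source, cycle_index).

    Events must be sorted by time; times are printed at millisecond precision.
    """
    times = [e.time_s for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("events must be sorted by time before writing")
    frame = pd.DataFrame(
        {
            "trial_id": [trial_id] * len(events),
            "side": [e.side for e in events],
            "kind": [e.kind for e in events],
            "time_s": [f"{e.time_s:.3f}" for e in events],
            "source": [e.source for e in events],
            "cycle_index": [e.cycle_index for e in events],
        }
    )
    frame.to_csv(path, index=False)


def read_events(path: str | Path) -> list[GaitEvent]:
    frame = pd.read_csv(path)
    required = {"side", "kind", "time_s", "source"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing event columns {sorted(missing)}")
    events = []
    for row in frame.itertuples(index=False):
        cycle = getattr(row, "cycle_index", None)
        if cycle is not None and (isinstance(cycle, float) and np.isnan(cycle)):
            cycle = None
        events.append(
            GaitEvent(
                time_s=float(row.time_s),
                kind=str(row.kind),
                side=str(row.side),
                source=str(row.source),
                cycle_index=None if cycle is None else int(cycle),
            )
        )
    return events


def write_params(params: Sequence[TemporalParams], path: str | Path, trial_id: str = "") -> None:
    """Write temporal parameters to CSV, one row per complete gait cycle."""
    frame = pd.DataFrame(
        {
            "trial_id": [trial_id] * len(params),
            "side": [p.side for p in params],
            "cycle_index": [p.cycle_index for p in params],
            "step_s": [p.step_time for p in params],
            "stride_s": [p.stride_time for p in params],
            "stance_s": [p.stance_time for p in params],
            "swing_s": [p.swing_time for p in params],
        }
    )
    frame.to_csv(path, index=False)


def read_params(path: str | Path) -> list[TemporalParams]:
    frame = pd.read_csv(path)
    params = []
    for row in frame.itertuples(index=False):
        step = float(row.step_s) if not pd.isna(row.step_s) else None
        params.append(
            TemporalParams(
                side=str(row.side),
                cycle_index=int(row.cycle_index),
                stride_time=float(row.stride_s),
                stance_time=float(row.stance_s),
                swing_time=float(row.swing_s),
                step_time=step,
            )
        )
    return params
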