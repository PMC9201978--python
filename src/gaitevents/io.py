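"""File I/O: marker trajectories (C3D and a CSV dialect), reference gait
events, and event/stride tables.

CSV trajectory dialect: one row per frame; a ``time_s`` column followed
by ``<MARKER>_x``, ``<MARKER>_y``, ``<MARKER>_z`` columns in meters.
Occluded samples are empty cells or NaN.  Frame indexing is 0-based and
an event's ``frame`` equals ``round(time * sampling_rate)`` relative to
the first sample.  No laboratory axis convention is assumed: detectors
work in the pelvis frame or with 3D magnitudes, so any right-handed
world frame is accepted.

C3D files are read through the minimal native codec; positions are
converted to meters using the file's declared POINT:UNITS (defaulting to
millimeters, the common convention for C3D).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from . import c3d as c3dmod
from .detectors import GaitEvent, GaitEventSet
from .trial import ALL_MARKERS, FOOT_MARKERS, MarkerTrialData

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}


class FileFormatError(IOError):
    """Raised on unparseable input files."""


def _normalize_label(label: str) -> str:
    return label.split(":")[-1].strip().upper()


# ----------------------------------------------------------------------
# trials
# ----------------------------------------------------------------------

def read_trial(path: str, format: str | None = None) -> MarkerTrialData:
    """Read marker trajectories from a C3D or CSV file (format inferred
    from the extension when not given).  Positions are converted to
    meters; occluded frames are flagged in the validity masks."""
    if format is None:
        format = "c3d" if os.path.splitext(path)[1].lower() == ".c3d" else "csv"
    if format == "c3d":
        trial = _read_trial_c3d(path)
    elif format == "csv":
        trial = _read_trial_csv(path)
    else:
        raise ValueError(f"unknown trial format {format!r}")
    missing = [m for m in FOOT_MARKERS if m not in trial.trajectories]
    if missing:
        raise FileFormatError(f"{path}: required foot markers missing: {missing}")
    return trial


def _read_trial_c3d(path: str) -> MarkerTrialData:
    data = c3dmod.read_c3d(path)
    scale = _UNIT_SCALE.get(data.units, 1e-3)
    n = data.points.shape[0]
    time = np.arange(n) / data.rate
    trajectories: dict[str, np.ndarray] = {}
    valid: dict[str, np.ndarray] = {}
    for j, label in enumerate(data.labels):
        name = _normalize_label(label)
        if name not in ALL_MARKERS:
            continue  # full-body marker sets: ignore extra markers
        xyz = data.points[:, j, :] * scale
        ok = (data.residuals[:, j] >= 0) & np.all(np.isfinite(xyz), axis=1)
        trajectories[name] = np.where(ok[:, None], xyz, np.nan)
        valid[name] = ok
    return MarkerTrialData(
        trial_id=os.path.splitext(os.path.basename(path))[0],
        sampling_rate=data.rate, time=time,
        trajectories=trajectories, valid_mask=valid)


def _read_trial_csv(path: str) -> MarkerTrialData:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FileFormatError(f"{path}: {exc}") from exc
    if "time_s" not in df.columns:
        raise FileFormatError(f"{path}: missing 'time_s' column")
    time = df["time_s"].to_numpy(float)
    if time.size < 2:
        raise FileFormatError(f"{path}: need at least two frames")
    rate = 1.0 / np.median(np.diff(time))
    trajectories: dict[str, np.ndarray] = {}
    for name in ALL_MARKERS:
        cols = [f"{name}_{ax}" for ax in "xyz"]
        if all(c in df.columns for c in cols):
            trajectories[name] = df[cols].to_numpy(float)
    return MarkerTrialData(
        trial_id=os.path.splitext(os.path.basename(path))[0],
        sampling_rate=round(rate, 6), time=time, trajectories=trajectories)


def write_trial_csv(trial: MarkerTrialData, path: str) -> None:
    """Write a trial in the CSV dialect (meters; occlusions as NaN)."""
    data = {"time_s": trial.time}
    for name, xyz in trial.trajectories.items():
        masked = np.where(trial.valid_mask[name][:, None], xyz, np.nan)
        for k, ax in enumerate("xyz"):
            data[f"{name}_{ax}"] = masked[:, k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9f")


def write_trial_c3d(trial: MarkerTrialData, path: str, units: str = "mm") -> None:
    """Write a trial as a float C3D file (positions scaled to ``units``)."""
    labels = sorted(trial.trajectories)
    scale = 1.0 / _UNIT_SCALE[units]
    points = np.stack([trial.trajectories[m] * scale for m in labels], axis=1)
    residuals = np.stack(
        [np.where(trial.valid_mask[m], 0.0, -1.0) for m in labels], axis=1)
    c3dmod.write_c3d(path, labels, points, rate=trial.sampling_rate,
                     units=units, residuals=residuals)


# ----------------------------------------------------------------------
# events
# ----------------------------------------------------------------------

def write_events(events: GaitEventSet, path: str) -> None:
    """Write an event table; a write-then-read round trip reproduces the
    set exactly (times printed with 6 decimals)."""
    events.to_dataframe().to_csv(path, index=False, float_format="%.6f")


def read_events(path: str) -> GaitEventSet:
    df = pd.read_csv(path)
    missing = set(GaitEventSet.COLUMNS) - set(df.columns)
    if missing:
        raise FileFormatError(f"{path}: missing event columns {sorted(missing)}")
    return GaitEventSet.from_dataframe(df)


def read_reference_events(path: str) -> GaitEventSet:
    """Read a reference event file: CSV with columns side, type, time_s
    (e.g. pressure-insole derived gold-standard events)."""
    df = pd.read_csv(path)
    for col in ("side", "type", "time_s"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column {col!r}")
    events = [
        GaitEvent(time=float(r.time_s), frame=-1, side=str(r.side).strip().upper(),
                  type=str(r.type).strip().upper(), method="reference")
        for r in df.itertuples()
    ]
    es = GaitEventSet(events)
    es.validate()
    return es


# ----------------------------------------------------------------------
# stride tables
# ----------------------------------------------------------------------

def write_stride_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def read_stride_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
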