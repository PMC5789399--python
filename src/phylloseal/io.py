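"""Delimited-text dialects for tracks, tensile records and result tables.

All interchange is plain UTF-8 CSV with "." decimals.  Floats are written
with ``repr`` (shortest round-trip form), so ``write . read`` is the
identity on canonical files, byte for byte.  Readers validate shape and
report malformed rows with their line numbers.

Track dialect (one file per leaf, MTrackJ-style flat export):
    frame_index,time_s,point_id,x,y          point_id in {1, 2, 3}
Tensile dialect:
    time_s,force_N,displacement_m            plus a 5-row geometry sidecar
    a_m,b_m
Repeated-measures table (long form):
    subject,condition,time_min,gamma_deg
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import AngleSeries, TrackSeries
from .tensile import LeafGeometry, TensileRecord, N_STATIONS

__all__ = [
    "write_tracks",
    "read_track",
    "read_tracks",
    "write_tensile",
    "read_tensile",
    "write_geometry",
    "read_geometry",
    "write_angle_table",
    "write_rm_table",
    "read_rm_table",
    "write_report",
]


def _fmt(x: float) -> str:
    return repr(float(x))


class MalformedRowError(ValueError):
    pass


def _parse_row(row, types, path, lineno):
    if len(row) != len(types):
        raise MalformedRowError(
            f"{path}:{lineno}: expected {len(types)} columns, got {len(row)}"
        )
    out = []
    for cell, typ in zip(row, types):
        try:
            out.append(typ(cell))
        except ValueError as exc:
            raise MalformedRowError(f"{path}:{lineno}: non-numeric field {cell!r}") from exc
    return out


# --------------------------------------------------------------------------
# tracks

def write_tracks(directory, tracks) -> list[Path]:
    """One ``tracks_<label>.csv`` per leaf; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for track in tracks:
        path = directory / f"tracks_{track.label}.csv"
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["frame_index", "time_s", "point_id", "x", "y"])
            for i, t in enumerate(track.times):
                for k in range(3):
                    w.writerow(
                        [i, _fmt(t), k + 1, _fmt(track.points[i, k, 0]), _fmt(track.points[i, k, 1])]
                    )
        paths.append(path)
    return paths


def read_track(path, units: str = "mm", y_down: bool = False) -> TrackSeries:
    """Read one per-leaf track file."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["frame_index", "time_s", "point_id", "x", "y"]:
            raise MalformedRowError(f"{path}:1: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            rows.append(_parse_row(row, [int, float, int, float, float], path, lineno))
    if not rows:
        raise MalformedRowError(f"{path}: empty track file")
    frames = sorted({r[0] for r in rows})
    n = len(frames)
    times = np.full(n, np.nan)
    points = np.full((n, 3, 2), np.nan)
    index = {f: i for i, f in enumerate(frames)}
    for frame, t, pid, x, y in rows:
        if pid not in (1, 2, 3):
            raise MalformedRowError(f"{path}: point_id {pid} outside 1..3")
        i = index[frame]
        times[i] = t
        points[i, pid - 1] = (x, y)
    if np.any(~np.isfinite(points)):
        raise MalformedRowError(f"{path}: some frames lack one of the 3 points")
    label = path.stem.removeprefix("tracks_")
    return TrackSeries(times, points, units=units, y_down=y_down, label=label)


def read_tracks(directory, units: str = "mm", y_down: bool = False) -> list[TrackSeries]:
    """Read every ``tracks_*.csv`` in a directory, sorted by label."""
    directory = Path(directory)
    paths = sorted(directory.glob("tracks_*.csv"))
    if not paths:
        raise FileNotFoundError(f"no tracks_*.csv in {directory}")
    return [read_track(p, units=units, y_down=y_down) for p in paths]


# --------------------------------------------------------------------------
# tensile

def write_tensile(path, record: TensileRecord) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "force_N", "displacement_m"])
        for t, f, d in zip(record.times, record.force, record.displacement):
            w.writerow([_fmt(t), _fmt(f), _fmt(d)])
    return path


def read_tensile(path, L0: float, label: str = "") -> TensileRecord:
    path = Path(path)
    t, f, d = [], [], []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["time_s", "force_N", "displacement_m"]:
            raise MalformedRowError(f"{path}:1: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            ti, fi, di = _parse_row(row, [float, float, float], path, lineno)
            t.append(ti)
            f.append(fi)
            d.append(di)
    return TensileRecord(np.array(t), np.array(f), np.array(d), L0, label=label or path.stem)


def write_geometry(path, geometry: LeafGeometry) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["a_m", "b_m"])
        for a, b in geometry.stations:
            w.writerow([_fmt(a), _fmt(b)])
    return path


def read_geometry(path) -> LeafGeometry:
    path = Path(path)
    stations = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["a_m", "b_m"]:
            raise MalformedRowError(f"{path}:1: unexpected header {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            stations.append(_parse_row(row, [float, float], path, lineno))
    if len(stations) != N_STATIONS:
        raise MalformedRowError(f"{path}: expected {N_STATIONS} stations, got {len(stations)}")
    return LeafGeometry(np.array(stations))


# --------------------------------------------------------------------------
# angle and repeated-measures tables

def write_angle_table(path, series: AngleSeries) -> Path:
    """Per-leaf angle table (degrees) on the frame grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame_index": np.arange(series.times.size),
            "time_s": series.times,
            "alpha_deg": series.alpha,
            "beta_deg": series.beta,
            "delta_deg": series.delta,
            "gamma_deg": series.gamma,
        }
    )
    df.to_csv(path, index=False)
    return path


def write_rm_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["subject", "condition", "time_min", "gamma_deg"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for _, row in table[cols].iterrows():
            w.writerow(
                [row["subject"], row["condition"], _fmt(row["time_min"]), _fmt(row["gamma_deg"])]
            )
    return path


def read_rm_table(path) -> pd.DataFrame:
    """Read the long-format repeated-measures table, rejecting duplicates."""
    path = Path(path)
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["subject", "condition", "time_min", "gamma_deg"]:
            raise MalformedRowError(f"{path}:1: unexpected header {header}")
        seen = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 4:
                raise MalformedRowError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            subject, condition = row[0], row[1]
            try:
                time_min = float(row[2])
                gamma = float(row[3])
            except ValueError as exc:
                raise MalformedRowError(f"{path}:{lineno}: non-numeric field") from exc
            key = (subject, condition, time_min)
            if key in seen:
                raise MalformedRowError(
                    f"{path}:{lineno}: duplicated cell key {key} (first at line {seen[key]})"
                )
            seen[key] = lineno
            rows.append((subject, condition, time_min, gamma))
    return pd.DataFrame(rows, columns=["subject", "condition", "time_min", "gamma_deg"])


def write_report(path, report: dict) -> Path:
    """Machine-readable JSON report (numbers only, no numpy scalars)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return path
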