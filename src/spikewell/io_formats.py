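"""Readers and writers for MEA text formats.

Supported inputs:

* Axion-style ``spike_list.csv`` — one row per spike with spike time (s),
  electrode name and amplitude (mV); with or without a header row.
* plate layout CSV — ``well,treatment`` rows.
* generic two-file format — a spike-times file (``electrode,time`` rows)
  plus an electrode-positions file (``electrode,x,y`` rows), for platforms
  other than Axion.

Aggregated feature tables (wells × recordings) are written one CSV per
feature with deterministic row/column ordering.
"""

from __future__ import annotations

import csv
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import PlateLayout, Recording, SpikeTrain, parse_electrode_id


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_spike_list(
    path: str | os.PathLike,
    start_time: float | None = None,
    end_time: float | None = None,
    label: str | None = None,
    strict: bool = False,
) -> Recording:
    """Read an Axion-style spike_list CSV into a :class:`Recording`.

    Each row holds ``time,electrode,amplitude``; a header row is detected
    and skipped. Non-monotone spike times within an electrode are sorted
    with a warning; malformed rows raise with the offending line number.
    With ``strict=True`` an input containing no spikes is an error.
    """
    path = Path(path)
    times: dict[str, list[float]] = {}
    amps: dict[str, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and not _is_number(row[0].strip()):
                continue  # header
            if len(row) < 2:
                raise ValueError(f"line {lineno}: expected time,electrode[,amplitude]")
            t_str, eid = row[0].strip(), row[1].strip()
            if not _is_number(t_str):
                raise ValueError(f"line {lineno}: unparseable spike time {t_str!r}")
            parse_electrode_id(eid)  # raises on malformed electrode name
            amp = np.nan
            if len(row) >= 3 and row[2].strip():
                if not _is_number(row[2].strip()):
                    raise ValueError(f"line {lineno}: unparseable amplitude {row[2]!r}")
                amp = float(row[2])
            times.setdefault(eid, []).append(float(t_str))
            amps.setdefault(eid, []).append(amp)
    if strict and not times:
        raise ValueError(f"{path}: no spikes found")
    trains = {}
    for eid, ts in times.items():
        arr = np.asarray(ts)
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            warnings.warn(f"electrode {eid}: spike times out of order; sorting")
        trains[eid] = SpikeTrain(eid, arr, np.asarray(amps[eid]))
    return Recording.from_trains(
        trains,
        start_time=start_time,
        end_time=end_time,
        label=label if label is not None else path.stem,
    )


def write_spike_list(recording: Recording, path: str | os.PathLike) -> Path:
    """Write a Recording back to spike_list.csv format (time-sorted rows)."""
    path = Path(path)
    rows = []
    for eid, tr in recording.trains.items():
        a = tr.amplitudes
        for i, t in enumerate(tr.times):
            amp = a[i] if a is not None and np.isfinite(a[i]) else ""
            rows.append((t, eid, amp))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["Time (s)", "Electrode", "Amplitude (mV)"])
        for t, eid, amp in rows:
            w.writerow([repr(float(t)), eid, amp])
    return path


def read_layout(path: str | os.PathLike) -> PlateLayout:
    """Read a ``well,treatment`` CSV; duplicate well rows are an error."""
    treatments: dict[str, str | None] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or all(not c.strip() for c in row):
                continue
            well = row[0].strip()
            if lineno == 1 and well.lower() in {"well", "well_id"}:
                continue
            if well in treatments:
                raise ValueError(f"line {lineno}: duplicate well {well!r}")
            treatment = row[1].strip() if len(row) > 1 and row[1].strip() else None
            treatments[well] = treatment
    return PlateLayout(treatments)


def write_layout(layout: PlateLayout, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["well", "treatment"])
        for well in sorted(layout.treatments):
            w.writerow([well, layout.treatments[well] or ""])
    return path


def read_generic_spikes(
    times_path: str | os.PathLike,
    positions_path: str | os.PathLike,
    start_time: float | None = None,
    end_time: float | None = None,
    label: str = "",
) -> Recording:
    """Read the generic two-file format (spike times + electrode positions).

    Electrodes listed in the positions file but absent from the times file
    are kept as empty trains; an electrode with spikes but no position is
    an error. Amplitudes are absent in this format.
    """
    positions: dict[str, tuple[float, float]] = {}
    with open(positions_path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            eid = row[0].strip()
            if lineno == 1 and not _is_number(row[1].strip() if len(row) > 1 else ""):
                continue
            if len(row) < 3:
                raise ValueError(f"positions line {lineno}: expected electrode,x,y")
            positions[eid] = (float(row[1]), float(row[2]))

    times: dict[str, list[float]] = {eid: [] for eid in positions}
    with open(times_path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            eid = row[0].strip()
            if lineno == 1 and len(row) > 1 and not _is_number(row[1].strip()):
                continue
            if eid not in positions:
                raise ValueError(
                    f"times line {lineno}: electrode {eid!r} missing from positions file"
                )
            if len(row) > 1 and row[1].strip():
                times[eid].append(float(row[1]))

    trains = {eid: SpikeTrain(eid, np.asarray(ts)) for eid, ts in times.items()}
    return Recording.from_trains(
        trains,
        start_time=start_time,
        end_time=end_time,
        label=label,
        electrode_positions=positions,
    )


def write_feature_tables(
    tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike
) -> list[Path]:
    """Write one CSV per feature (wells as rows, recordings as columns).

    Rows are sorted by well label and columns by recording label so output
    is deterministic; missing cells are left empty.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for feature in sorted(tables):
        df = tables[feature].sort_index()
        df = df[sorted(df.columns)]
        p = out_dir / f"{feature}.csv"
        df.to_csv(p, index_label="well")
        paths.append(p)
    return paths
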