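"""Tabular readers and writers.

All files are UTF-8 comma-delimited text with a header row naming the
columns; lines starting with ``#`` are comments.  Column names carry
explicit units:

* TAC table: ``frame_start_s, frame_duration_s`` then one column per
  region holding frame-averaged activity in kBq/cc.
* Blood table: ``time_min, whole_blood_kBq_cc, plasma_kBq_cc, source``
  (plasma may be blank; source is ``automatic`` or ``manual``).
* Parent table: ``time_min, parent_fraction``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BloodSampleTable, FrameSchedule, ParentFractionTable, TimeActivityCurve
from .errors import FormatError

_TAC_META = ("frame_start_s", "frame_duration_s")


def _read_csv(path) -> pd.DataFrame:
    try:
        # round_trip parsing so write -> read is bit-lossless
        return pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _require(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_tac_table(path) -> list[TimeActivityCurve]:
    """Read one TAC per region column; all share the file's schedule."""
    df = _read_csv(path)
    _require(df, _TAC_META, path)
    regions = [c for c in df.columns if c not in _TAC_META]
    if not regions:
        raise FormatError(f"{path}: no region columns")
    schedule = FrameSchedule(df["frame_start_s"].to_numpy(), df["frame_duration_s"].to_numpy())
    return [
        TimeActivityCurve(schedule, df[r].to_numpy(dtype=float), region_label=r)
        for r in regions
    ]


def write_tac_table(path, tacs: list[TimeActivityCurve]) -> None:
    sched = tacs[0].schedule
    for tac in tacs[1:]:
        if tac.schedule.n_frames != sched.n_frames or not np.allclose(
            tac.schedule.frame_start_s, sched.frame_start_s
        ):
            raise FormatError("all TACs in one table must share a schedule")
    cols = {
        "frame_start_s": sched.frame_start_s,
        "frame_duration_s": sched.frame_duration_s,
    }
    for tac in tacs:
        cols[tac.region_label] = tac.activity
    _write_df(path, pd.DataFrame(cols))


def read_blood_table(path) -> list[BloodSampleTable]:
    """Read blood samples, one :class:`BloodSampleTable` per source present."""
    df = _read_csv(path)
    _require(df, ("time_min", "whole_blood_kBq_cc"), path)
    if "source" not in df.columns:
        df = df.assign(source="manual")
    out = []
    for source, grp in df.groupby("source", sort=True):
        t = grp["time_min"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise FormatError(f"{path}: non-monotone time at {source} sample {bad}")
        plasma = None
        if "plasma_kBq_cc" in grp.columns and grp["plasma_kBq_cc"].notna().any():
            plasma = grp["plasma_kBq_cc"].to_numpy(dtype=float)
        out.append(
            BloodSampleTable(t, grp["whole_blood_kBq_cc"].to_numpy(dtype=float), plasma, str(source))
        )
    return out


def write_blood_table(path, tables: list[BloodSampleTable]) -> None:
    frames = []
    for tbl in tables:
        plasma = tbl.plasma_kbq_cc if tbl.plasma_kbq_cc is not None else np.full_like(tbl.time_min, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "time_min": tbl.time_min,
                    "whole_blood_kBq_cc": tbl.whole_blood_kbq_cc,
                    "plasma_kBq_cc": plasma,
                    "source": tbl.source,
                }
            )
        )
    _write_df(path, pd.concat(frames, ignore_index=True))


def read_parent_table(path) -> ParentFractionTable:
    df = _read_csv(path)
    _require(df, ("time_min", "parent_fraction"), path)
    t = df["time_min"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: non-monotone parent-fraction times")
    return ParentFractionTable(t, df["parent_fraction"].to_numpy(dtype=float))


def write_parent_table(path, table: ParentFractionTable) -> None:
    _write_df(
        path,
        pd.DataFrame({"time_min": table.time_min, "parent_fraction": table.parent_fraction}),
    )


def _write_df(path, df: pd.DataFrame) -> None:
    # repr-precision floats so write -> read round-trips exactly
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format="%.17g")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")
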