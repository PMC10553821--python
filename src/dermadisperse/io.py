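"""Readers and writers for the tabular formats the pipeline consumes.

Track tables are plain CSV/TSV (or one sheet of an xlsx workbook, selected
through a dialect descriptor) with columns
``track_id,lineage_id,role,t_min,x_um,y_um[,z_um][,division_time_min]``;
condensate tables are CSV with ``id,cx_um,cy_um,radius_um``.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import (
    CondensateMap,
    ROLES,
    SchemaError,
    Track,
    TrackSet,
    ValidationError,
    extent_of,
)

TRACK_COLUMNS = ("track_id", "lineage_id", "role", "t_min", "x_um", "y_um")
CONDENSATE_COLUMNS = ("id", "cx_um", "cy_um", "radius_um")


def _load_table(path, dialect: Optional[dict]) -> pd.DataFrame:
    dialect = dialect or {}
    fmt = dialect.get("format")
    if fmt is None:
        s = str(path)
        fmt = "xlsx" if s.endswith((".xlsx", ".xls")) else ("tsv" if s.endswith(".tsv") else "csv")
    if fmt == "xlsx":
        df = pd.read_excel(path, sheet_name=dialect.get("sheet", 0))
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    columns = dialect.get("columns")
    if columns:  # map source headers onto the standard schema
        df = df.rename(columns={v: k for k, v in columns.items()})
    return df


def read_track_table(path, dialect: Optional[dict] = None) -> TrackSet:
    """Read a track table into a validated :class:`TrackSet`.

    The frame interval is inferred as the modal consecutive time difference
    across all tracks; gaps (multiples of it) are retained.
    """
    df = _load_table(path, dialect)
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"track table {path}: missing column {col!r}")
    tracks = []
    diffs = []
    for track_id, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_min")
        role = str(g["role"].iloc[0])
        if role not in ROLES:
            raise ValidationError(f"track {track_id!r}: unknown role {role!r}")
        t = g["t_min"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError(f"track {track_id!r}: non-monotone times")
        division_time = None
        if "division_time_min" in g.columns:
            dv = g["division_time_min"].iloc[0]
            if pd.notna(dv):
                division_time = float(dv)
        tracks.append(
            Track(
                track_id=str(track_id),
                lineage_id=str(g["lineage_id"].iloc[0]),
                role=role,
                t=t,
                x=g["x_um"].to_numpy(dtype=float),
                y=g["y_um"].to_numpy(dtype=float),
                z=g["z_um"].to_numpy(dtype=float) if "z_um" in g.columns else None,
                division_time=division_time,
            )
        )
        if len(t) > 1:
            diffs.append(np.diff(t))
    if diffs:
        alldiff = np.concatenate(diffs)
        vals, counts = np.unique(np.round(alldiff, 6), return_counts=True)
        frame_interval = float(vals[np.argmax(counts)])
    else:
        frame_interval = 1.0
        if tracks:
            warnings.warn("no consecutive frames found; frame interval defaults to 1 min")
    extent = extent_of([tr.x for tr in tracks], [tr.y for tr in tracks])
    ts = TrackSet(tracks=tracks, frame_interval=frame_interval, field_extent=extent)
    ts.validate()
    return ts


def write_track_table(trackset: TrackSet, path) -> None:
    """Write a TrackSet in the standard schema (CSV; re-readable)."""
    rows = []
    for tr in trackset.tracks:
        for i in range(tr.n_points):
            row = {
                "track_id": tr.track_id,
                "lineage_id": tr.lineage_id,
                "role": tr.role,
                "t_min": tr.t[i],
                "x_um": tr.x[i],
                "y_um": tr.y[i],
            }
            if tr.z is not None:
                row["z_um"] = tr.z[i]
            if tr.division_time is not None:
                row["division_time_min"] = tr.division_time
            rows.append(row)
    cols = list(TRACK_COLUMNS)
    if any(tr.z is not None for tr in trackset.tracks):
        cols.append("z_um")
    if any(tr.division_time is not None for tr in trackset.tracks):
        cols.append("division_time_min")
    write_results_table(rows, path, columns=cols)


def read_condensate_map(path, dialect: Optional[dict] = None) -> CondensateMap:
    """Read a condensate geometry table (``id,cx_um,cy_um,radius_um``)."""
    df = _load_table(path, dialect)
    for col in CONDENSATE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"condensate table {path}: missing column {col!r}")
    return CondensateMap(
        ids=[str(v) for v in df["id"]],
        cx=df["cx_um"].to_numpy(dtype=float),
        cy=df["cy_um"].to_numpy(dtype=float),
        radius=df["radius_um"].to_numpy(dtype=float),
    )


def write_condensate_map(cmap: CondensateMap, path) -> None:
    rows = [
        {"id": cid, "cx_um": cx, "cy_um": cy, "radius_um": r}
        for cid, cx, cy, r in zip(cmap.ids, cmap.cx, cmap.cy, cmap.radius)
    ]
    if not rows:
        rows = []
    df = pd.DataFrame(rows, columns=list(CONDENSATE_COLUMNS))
    df.to_csv(path, index=False, float_format="%.12g")


def write_results_table(records, path, columns=None) -> None:
    """Write result records as CSV with a stable column order and 12
    significant digits, so written tables round-trip numerically.

    ``columns`` fixes the header for an empty record list.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        cols = columns if columns is not None else (list(records[0].keys()) if records else [])
        df = pd.DataFrame(records, columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")
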