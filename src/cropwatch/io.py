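"""CSV readers and writers for detection, log and event tables.

All files are comma-separated UTF-8 with ISO 8601 dates (YYYY-MM-DD)
and times (HH:MM:SS); datetimes are naive local time.  Every reader
returns a time-ordered DataFrame together with a :class:`ReadReport`
accounting for each input row: rows that violate the schema are
rejected (counted and reported, never silently dropped), rows that are
legal but suspicious are kept and flagged.  With ``strict=True`` any
rejected row raises instead.
"""

from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DETECTION_COLUMNS,
    EVENT_COLUMNS,
    GUARD_COLUMNS,
    METHODS,
    RESEARCHER_COLUMNS,
    SPECIES,
    STATION_COLUMNS,
    CameraStation,
    ReadReport,
    RowError,
    SchemaError,
    validate_stations,
)

logger = logging.getLogger(__name__)


def _read_raw(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    return raw


def _finish(
    frame: pd.DataFrame,
    n_input: int,
    rejected: list[str],
    flagged: list[str],
    strict: bool,
) -> tuple[pd.DataFrame, ReadReport]:
    if strict and rejected:
        raise RowError("; ".join(rejected))
    for msg in rejected + flagged:
        logger.warning(msg)
    report = ReadReport(
        n_input=n_input,
        n_accepted=len(frame),
        n_rejected=len(rejected),
        n_flagged=len(flagged),
        warnings=tuple(rejected + flagged),
    )
    return frame, report


def _parse_datetime(value: str) -> dt.datetime:
    return dt.datetime.fromisoformat(value.strip())


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def _parse_time(value: str) -> dt.time:
    return dt.time.fromisoformat(value.strip())


def read_stations_csv(path: str | Path) -> list[CameraStation]:
    """Read camera station positions (station_id, position_m, view_start_m, view_end_m)."""
    raw = _read_raw(path, STATION_COLUMNS)
    stations = [
        CameraStation(
            station_id=str(r.station_id),
            position_m=float(r.position_m),
            view_start_m=float(r.view_start_m),
            view_end_m=float(r.view_end_m),
        )
        for r in raw.itertuples()
    ]
    return validate_stations(stations)


def read_camera_csv(
    path: str | Path,
    stations: list[CameraStation] | None = None,
    strict: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read camera photograph records (station_id, datetime, species).

    Rows with unknown station ids or species (including unidentifiable
    species codes) are rejected with a warning; the report counts them.
    Returns detections sorted by (timestamp, station_id).
    """
    raw = _read_raw(path, ["station_id", "datetime", "species"])
    known = {s.station_id for s in stations} if stations is not None else None
    rows, rejected, flagged = [], [], []
    for i, r in enumerate(raw.itertuples(), start=2):  # header is line 1
        sid = str(r.station_id).strip()
        sp = str(r.species).strip().lower()
        if known is not None and sid not in known:
            rejected.append(f"line {i}: unknown station_id {sid!r}")
            continue
        if sp not in SPECIES:
            rejected.append(f"line {i}: unknown species {sp!r}")
            continue
        try:
            ts = _parse_datetime(str(r.datetime))
        except ValueError:
            rejected.append(f"line {i}: unparseable datetime {r.datetime!r}")
            continue
        rows.append((sid, ts, sp))
    frame = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    frame = frame.sort_values(["timestamp", "station_id"], kind="stable").reset_index(
        drop=True
    )
    return _finish(frame, len(raw), rejected, flagged, strict)


def read_guard_csv(
    path: str | Path,
    window: tuple[dt.time, dt.time] = (dt.time(6), dt.time(18)),
    strict: bool = False,
) -> tuple[pd.DataFrame, ReadReport]:
    """Read the guard's log (date, time, species).

    Records outside the duty window are kept but flagged via the
    ``out_of_window`` column (the guard may have logged late).
    """
    raw = _read_raw(path, GUARD_COLUMNS)
    rows, rejected, flagged = [], [], []
    for i, r in enumerate(raw.itertuples(), start=2):
        sp = str(r.species).strip().lower()
        if sp not in SPECIES:
            rejected.append(f"line {i}: unknown species {sp!r}")
            continue
        try:
            d = _parse_date(str(r.date))
            t = _parse_time(str(r.time))
        except ValueError:
            rejected.append(f"line {i}: unparseable date/time {r.date!r} {r.time!r}")
            continue
        oow = not (window[0] <= t <= window[1])
        if oow:
            flagged.append(f"line {i}: time {t} outside duty window")
        rows.append((d, t, sp, oow))
    frame = pd.DataFrame(rows, columns=GUARD_COLUMNS + ["out_of_window"])
    frame = frame.sort_values(["date", "time"], kind="stable").reset_index(drop=True)
    return _finish(frame, len(raw), rejected, flagged, strict)


def read_researcher_csv(
    path: str | Path, strict: bool = False
) -> tuple[pd.DataFrame, ReadReport]:
    """Read researcher event records.

    Schema: date, entry_time, exit_time, species, items_removed.  An
    empty items_removed cell means the count was not recorded — a legal
    state distinct from zero (such events still count as events but are
    excluded from crop-item sums downstream).  Exit before entry is a
    row error.
    """
    raw = _read_raw(path, RESEARCHER_COLUMNS)
    rows, rejected, flagged = [], [], []
    for i, r in enumerate(raw.itertuples(), start=2):
        sp = str(r.species).strip().lower()
        if sp not in SPECIES:
            rejected.append(f"line {i}: unknown species {sp!r}")
            continue
        try:
            d = _parse_date(str(r.date))
            entry = _parse_time(str(r.entry_time))
            exit_ = _parse_time(str(r.exit_time))
        except ValueError:
            rejected.append(f"line {i}: unparseable date/time fields")
            continue
        if exit_ < entry:
            rejected.append(f"line {i}: exit_time {exit_} before entry_time {entry}")
            continue
        items_raw = str(r.items_removed).strip()
        if items_raw == "":
            items: int | None = None
        else:
            try:
                items = int(items_raw)
            except ValueError:
                rejected.append(f"line {i}: non-integer items_removed {items_raw!r}")
                continue
            if items < 0:
                rejected.append(f"line {i}: negative items_removed {items}")
                continue
        rows.append((d, entry, exit_, sp, items))
    frame = pd.DataFrame(rows, columns=RESEARCHER_COLUMNS)
    frame["items_removed"] = pd.array(
        [x if x is not None else pd.NA for x in frame["items_removed"]], dtype="Int64"
    )
    frame = frame.sort_values(["date", "entry_time"], kind="stable").reset_index(
        drop=True
    )
    return _finish(frame, len(raw), rejected, flagged, strict)


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    """Write an EventRecord table; round-trips losslessly through read_events_csv."""
    out = events.loc[:, EVENT_COLUMNS].copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    end = pd.to_datetime(out["end"])
    out["end"] = end.dt.strftime("%Y-%m-%dT%H:%M:%S").where(end.notna(), "")
    out.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Read an EventRecord table written by :func:`write_events_csv`."""
    raw = _read_raw(path, EVENT_COLUMNS)
    frame = pd.DataFrame(
        {
            "method": raw["method"].astype(str),
            "species": raw["species"].astype(str),
            "start": pd.to_datetime(raw["start"]),
            "end": pd.to_datetime(raw["end"].replace("", pd.NaT)),
            "items_removed": pd.array(
                [int(x) if x != "" else pd.NA for x in raw["items_removed"]],
                dtype="Int64",
            ),
            "n_detections": pd.array(
                [int(x) if x != "" else pd.NA for x in raw["n_detections"]],
                dtype="Int64",
            ),
        }
    )
    bad = set(frame["method"]) - set(METHODS)
    if bad:
        raise SchemaError(f"{path}: unknown methods {sorted(bad)}")
    return frame.sort_values(["method", "species", "start"], kind="stable").reset_index(
        drop=True
    )


def empty_events() -> pd.DataFrame:
    """An empty EventRecord table with the correct dtypes."""
    return pd.DataFrame(
        {
            "method": pd.Series(dtype=str),
            "species": pd.Series(dtype=str),
            "start": pd.Series(dtype="datetime64[ns]"),
            "end": pd.Series(dtype="datetime64[ns]"),
            "items_removed": pd.Series(dtype="Int64"),
            "n_detections": pd.Series(dtype="Int64"),
        }
    )


def write_detections_csv(detections: pd.DataFrame, path: str | Path) -> None:
    out = detections.loc[:, DETECTION_COLUMNS].copy()
    out = out.rename(columns={"timestamp": "datetime"})
    out["datetime"] = pd.to_datetime(out["datetime"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def write_guard_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, GUARD_COLUMNS].to_csv(path, index=False)


def write_researcher_csv(records: pd.DataFrame, path: str | Path) -> None:
    records.loc[:, RESEARCHER_COLUMNS].to_csv(path, index=False)


def write_stations_csv(stations: list[CameraStation], path: str | Path) -> None:
    pd.DataFrame(
        [
            (s.station_id, s.position_m, s.view_start_m, s.view_end_m)
            for s in stations
        ],
        columns=STATION_COLUMNS,
    ).to_csv(path, index=False)
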