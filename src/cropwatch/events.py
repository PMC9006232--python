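"""Delineation of independent crop-foraging events per method.

Two independence rules are implemented:

* Camera photographs: a photo starts a new event iff at least
  ``camera_window_min`` minutes (default 30) have passed since the
  previous photo of the *same species* on *any* of the pooled cameras.
  The 30-min window reflects field observation that incursions rarely
  last longer than 30 minutes.  Photos of different species never share
  an event.
* Observer records (guard, researcher): successive same-species records
  closer than ``obs_gap_min`` minutes (default 1, the "one minute of
  empty field" rule) are merged into one event.

The camera scan runs over the full deployment stream, crossing midnight
freely (cameras record around the clock); an event is attributed to the
day of its first photograph.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .io import empty_events
from .types import ClusteringConfig, DutyCalendar, RowError, SPECIES


def cluster_detections(
    detections: pd.DataFrame,
    config: ClusteringConfig = ClusteringConfig(),
    stations_subset: set[str] | None = None,
) -> pd.DataFrame:
    """Greedy chronological clustering of pooled camera photographs.

    Per species, scanning photos in (timestamp, station_id) order, a
    photo opens a new event iff its gap to the immediately preceding
    photo of the same species is >= camera_window_min ("at least 30
    minutes had passed": a gap exactly equal to the window separates).
    Event start/end are the first/last photo times; n_detections counts
    the photos merged.
    """
    if stations_subset is not None:
        detections = detections[detections["station_id"].isin(stations_subset)]
    if detections.empty:
        return empty_events()
    window = pd.Timedelta(minutes=config.camera_window_min)
    df = detections.sort_values(["timestamp", "station_id"], kind="stable")
    out = []
    for sp, grp in df.groupby("species", sort=True):
        ts = grp["timestamp"].to_numpy()
        gaps = np.diff(ts)
        # new event where the photo-to-photo gap reaches the window
        new = np.concatenate([[True], gaps >= np.timedelta64(window.to_timedelta64())])
        labels = np.cumsum(new)
        for _, photos in pd.Series(ts).groupby(labels):
            out.append(
                (
                    "camera",
                    sp,
                    photos.iloc[0],
                    photos.iloc[-1],
                    pd.NA,
                    len(photos),
                )
            )
    events = pd.DataFrame(
        out, columns=["method", "species", "start", "end", "items_removed", "n_detections"]
    )
    events["items_removed"] = pd.array(events["items_removed"], dtype="Int64")
    events["n_detections"] = events["n_detections"].astype("Int64")
    return events.sort_values(["species", "start"], kind="stable").reset_index(drop=True)


def _combine(date, time) -> dt.datetime:
    return dt.datetime.combine(date, time)


def guard_records_to_events(
    records: pd.DataFrame, config: ClusteringConfig = ClusteringConfig()
) -> pd.DataFrame:
    """One guard log line = one event, after collapsing near-duplicates.

    Guards log event start times; per species, consecutive records
    closer than obs_gap_min minutes are merged (the field cannot have
    emptied in between).  obs_gap_min = 0 takes the log verbatim.
    """
    if records.empty:
        return empty_events()
    gap = dt.timedelta(minutes=config.obs_gap_min)
    rows = []
    for sp, grp in records.groupby("species", sort=True):
        times = sorted(_combine(r.date, r.time) for r in grp.itertuples())
        current = [times[0]]
        for t in times[1:]:
            if t - current[-1] < gap:
                current.append(t)
            else:
                rows.append(("guard", sp, current[0], pd.NaT, pd.NA, pd.NA))
                current = [t]
        rows.append(("guard", sp, current[0], pd.NaT, pd.NA, pd.NA))
    events = pd.DataFrame(
        rows, columns=["method", "species", "start", "end", "items_removed", "n_detections"]
    )
    events["start"] = pd.to_datetime(events["start"])
    events["end"] = pd.to_datetime(events["end"])
    events["items_removed"] = pd.array(events["items_removed"], dtype="Int64")
    events["n_detections"] = pd.array(events["n_detections"], dtype="Int64")
    return events.sort_values(["species", "start"], kind="stable").reset_index(drop=True)


def researcher_records_to_events(
    records: pd.DataFrame, config: ClusteringConfig = ClusteringConfig()
) -> pd.DataFrame:
    """Researcher records to events, merging across sub-minute gaps.

    Same-species events whose gap (previous exit to next entry) is
    shorter than obs_gap_min are one incursion by the field definition
    and are merged; item counts sum, with a missing count propagating
    (missing + x = missing).  Overlapping same-species records violate
    the event definition and raise.
    """
    if records.empty:
        return empty_events()
    gap = dt.timedelta(minutes=config.obs_gap_min)
    rows = []
    for sp, grp in records.sort_values(["date", "entry_time"], kind="stable").groupby(
        "species", sort=True
    ):
        intervals = [
            (
                _combine(r.date, r.entry_time),
                _combine(r.date, r.exit_time),
                r.items_removed,
            )
            for r in grp.itertuples()
        ]
        cur_start, cur_end, cur_items = intervals[0]
        for start, end, items in intervals[1:]:
            if start < cur_end:
                raise RowError(
                    f"overlapping researcher events for {sp} at {start.isoformat()}"
                )
            if start - cur_end < gap:
                cur_end = max(cur_end, end)
                cur_items = (
                    pd.NA
                    if pd.isna(cur_items) or pd.isna(items)
                    else int(cur_items) + int(items)
                )
            else:
                rows.append(("researcher", sp, cur_start, cur_end, cur_items, pd.NA))
                cur_start, cur_end, cur_items = start, end, items
        rows.append(("researcher", sp, cur_start, cur_end, cur_items, pd.NA))
    events = pd.DataFrame(
        rows, columns=["method", "species", "start", "end", "items_removed", "n_detections"]
    )
    events["start"] = pd.to_datetime(events["start"])
    events["end"] = pd.to_datetime(events["end"])
    events["items_removed"] = pd.array(events["items_removed"], dtype="Int64")
    events["n_detections"] = pd.array(events["n_detections"], dtype="Int64")
    return events.sort_values(["species", "start"], kind="stable").reset_index(drop=True)


def daily_event_counts(
    events: pd.DataFrame,
    calendar: DutyCalendar,
    diurnal_only: bool = True,
) -> pd.DataFrame:
    """Per duty-date, per-species event counts, zero-filled.

    Duty dates with no events appear with count 0 (zero is data);
    non-duty dates are absent (missing, not zero).  An event on a
    non-duty date signals an upstream invariant breach and raises.
    With ``diurnal_only`` camera events starting outside 06:00-18:00
    are excluded, since the observer methods cannot record then.
    """
    ev = events
    if diurnal_only and not ev.empty:
        tod = pd.to_datetime(ev["start"]).dt.time
        ev = ev[(tod >= dt.time(6, 0)) & (tod < dt.time(18, 0))]
    duty = sorted(calendar.dates)
    if not ev.empty:
        ev_dates = pd.to_datetime(ev["start"]).dt.date
        off_duty = set(ev_dates) - set(duty)
        if off_duty:
            raise RowError(
                f"{calendar.method} events on non-duty dates: {sorted(off_duty)[:3]}"
            )
        counted = (
            pd.DataFrame({"date": ev_dates, "species": ev["species"]})
            .groupby(["date", "species"])
            .size()
        )
    else:
        counted = pd.Series(dtype="int64")
    index = pd.MultiIndex.from_product([duty, sorted(SPECIES)], names=["date", "species"])
    counts = counted.reindex(index, fill_value=0).astype("int64")
    out = counts.rename("n_events").reset_index()
    out.insert(0, "method", calendar.method)
    return out
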