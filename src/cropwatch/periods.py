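"""Matched-day filtering and ten-day period aggregation.

Methods differ in when they were recording (researchers about five
days a week, guard and cameras daily), so raw daily counts are not
comparable.  All per-period means are therefore taken over *matched
days*: calendar days on which every compared method was on duty.  If
researchers were absent two days of a ten-day period, guard and camera
values for those days are removed too and the mean runs over the eight
remaining days.

The study window is divided into consecutive ten-day periods anchored
at its first day; a trailing partial period is dropped (and logged).
"""

from __future__ import annotations

import datetime as dt
import logging

import pandas as pd

from .types import DutyCalendar, SPECIES

logger = logging.getLogger(__name__)

MEASURES = ("events_per_day", "items_per_day")


def build_periods(
    start_date: dt.date, end_date: dt.date, period_len_days: int = 10
) -> pd.DataFrame:
    """Map each date of the window to a period index from the start.

    Returns a frame (date, period_index) covering only full periods;
    a trailing partial block is dropped with a warning.  A window
    shorter than one period is an error.
    """
    if period_len_days < 1:
        raise ValueError("period_len_days must be >= 1")
    n_days = (end_date - start_date).days + 1
    if n_days < period_len_days:
        raise ValueError(
            f"range of {n_days} days is shorter than one {period_len_days}-day period"
        )
    n_periods = n_days // period_len_days
    dropped = n_days - n_periods * period_len_days
    if dropped:
        logger.warning("dropping %d trailing days not filling a period", dropped)
    dates = [
        start_date + dt.timedelta(days=i) for i in range(n_periods * period_len_days)
    ]
    return pd.DataFrame(
        {"date": dates, "period_index": [i // period_len_days for i in range(len(dates))]}
    )


def matched_days(calendars: dict[str, DutyCalendar]) -> set[dt.date]:
    """Days on which every method was recording (intersection of duty sets)."""
    if not calendars:
        raise ValueError("at least one duty calendar required")
    matched: set[dt.date] | None = None
    for cal in calendars.values():
        matched = set(cal.dates) if matched is None else matched & set(cal.dates)
    assert matched is not None
    if not matched:
        limiting = min(calendars.values(), key=lambda c: len(c.dates))
        raise ValueError(
            f"no day is covered by all methods; {limiting.method} is the limiting calendar"
        )
    return matched


def crop_loss_daily(
    researcher_events: pd.DataFrame, calendar: DutyCalendar
) -> pd.DataFrame:
    """Daily crop items removed per species, from researcher events.

    Sums items_removed over events with a KNOWN count only; events with
    an unrecorded count still count as crop-foraging events elsewhere
    but contribute nothing here.  ``n_excluded`` records per day/species
    how many events were dropped from the item sum.
    """
    duty = sorted(calendar.dates)
    index = pd.MultiIndex.from_product([duty, sorted(SPECIES)], names=["date", "species"])
    if researcher_events.empty:
        out = pd.DataFrame(index=index).reset_index()
        out["items"] = 0
        out["n_excluded"] = 0
        out.insert(0, "method", "researcher")
        return out
    items = researcher_events["items_removed"]
    if (items.dropna() < 0).any():
        raise ValueError("negative items_removed")
    df = pd.DataFrame(
        {
            "date": pd.to_datetime(researcher_events["start"]).dt.date,
            "species": researcher_events["species"],
            "known": items.fillna(0).astype("int64"),
            "excluded": items.isna().astype("int64"),
        }
    )
    grouped = df.groupby(["date", "species"]).agg(
        items=("known", "sum"), n_excluded=("excluded", "sum")
    )
    out = grouped.reindex(index, fill_value=0).astype("int64").reset_index()
    out.insert(0, "method", "researcher")
    return out


def aggregate_to_periods(
    daily: dict[tuple[str, str], pd.DataFrame],
    matched: set[dt.date],
    periods: pd.DataFrame,
) -> pd.DataFrame:
    """Mean daily value of each measure per period over matched days.

    ``daily`` maps (method, measure) to a zero-filled per-duty-day table
    with columns (date, species, value-column).  Output: one row per
    period x species x method x measure with the arithmetic mean over
    that period's matched days and the matched-day count; periods with
    no matched days are dropped with a warning.
    """
    period_of = dict(zip(periods["date"], periods["period_index"]))
    rows = []
    for (method, measure), table in daily.items():
        value_col = "n_events" if measure == "events_per_day" else "items"
        df = table[table["date"].isin(matched)].copy()
        df["period_index"] = df["date"].map(period_of)
        df = df.dropna(subset=["period_index"])
        for (pi, sp), grp in df.groupby(["period_index", "species"]):
            rows.append(
                (
                    int(pi),
                    sp,
                    method,
                    measure,
                    float(grp[value_col].mean()),
                    int(len(grp)),
                )
            )
    out = pd.DataFrame(
        rows,
        columns=["period_index", "species", "method", "measure", "value", "n_matched_days"],
    )
    all_periods = set(periods["period_index"])
    seen = set(out["period_index"])
    for missing in sorted(all_periods - seen):
        logger.warning("period %d has no matched days; dropped", missing)
    return out.sort_values(
        ["measure", "method", "species", "period_index"], kind="stable"
    ).reset_index(drop=True)
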