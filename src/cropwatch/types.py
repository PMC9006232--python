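"""Domain types shared across the crop-foraging monitoring pipeline.

The pipeline compares three detection methods operating on the same
1-ha field: motion-triggered camera traps on the field edge, a crop
guard logging incursions, and researchers observing from a hide.  All
tables are pandas DataFrames with the column schemas declared here;
small value-like objects are frozen dataclasses.

Datetimes are naive local time throughout (the study region has no
daylight-saving transitions); a calendar day runs midnight to midnight.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

SPECIES = ("baboon", "vervet")
METHODS = ("camera", "guard", "researcher")

#: Diurnal window during which guards and researchers can observe.
DAY_START = dt.time(6, 0, 0)
DAY_END = dt.time(18, 0, 0)

# Column schemas for the tabular types.  Readers/writers and the
# clustering/aggregation stages all agree on these names.
DETECTION_COLUMNS = ["station_id", "timestamp", "species"]
GUARD_COLUMNS = ["date", "time", "species"]
RESEARCHER_COLUMNS = ["date", "entry_time", "exit_time", "species", "items_removed"]
EVENT_COLUMNS = ["method", "species", "start", "end", "items_removed", "n_detections"]
TRUTH_COLUMNS = [
    "event_id",
    "species",
    "start",
    "duration_min",
    "group_size",
    "entry_position_m",
    "items_removed",
]
STATION_COLUMNS = ["station_id", "position_m", "view_start_m", "view_end_m"]


class SchemaError(ValueError):
    """A CSV file does not match its documented schema."""


class RowError(ValueError):
    """A row violates an invariant that cannot be repaired."""


@dataclass(frozen=True)
class CameraStation:
    """A camera trap position along the field edge.

    Positions are metres from the southerly corner of the field; the
    view interval is the closed stretch of edge the camera can see.
    """

    station_id: str
    position_m: float
    view_start_m: float
    view_end_m: float

    def __post_init__(self) -> None:
        if self.position_m < 0:
            raise ValueError(f"station {self.station_id}: position_m must be >= 0")
        if not self.view_end_m > self.view_start_m:
            raise ValueError(
                f"station {self.station_id}: view interval must have positive length"
            )

    def covers(self, position_m: float) -> bool:
        return self.view_start_m <= position_m <= self.view_end_m


def validate_stations(stations: list[CameraStation]) -> list[CameraStation]:
    ids = [s.station_id for s in stations]
    if len(set(ids)) != len(ids):
        raise ValueError("station_ids must be unique")
    return stations


@dataclass(frozen=True)
class DutyCalendar:
    """Dates and daily time window during which a method was recording.

    Absence from the calendar means missing data for that day, never
    zero events; only duty days may carry event counts downstream.
    """

    method: str
    dates: frozenset[dt.date]
    window_start: dt.time = DAY_START
    window_end: dt.time = DAY_END

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    def on_duty(self, date: dt.date) -> bool:
        return date in self.dates

    def in_window(self, time: dt.time) -> bool:
        return self.window_start <= time <= self.window_end


@dataclass(frozen=True)
class ClusteringConfig:
    """Independence rules delineating separate crop-foraging events.

    camera_window_min: a photograph starts a new event iff at least
    this many minutes passed since the previous photo of the same
    species on any pooled camera (default 30).
    obs_gap_min: observer records (guard/researcher) closer than this
    are merged into one event (default 1; 0 disables merging).
    """

    camera_window_min: float = 30.0
    obs_gap_min: float = 1.0

    def __post_init__(self) -> None:
        if self.camera_window_min <= 0:
            raise ValueError("camera_window_min must be > 0")
        if self.obs_gap_min < 0:
            raise ValueError("obs_gap_min must be >= 0")


@dataclass(frozen=True)
class ReadReport:
    """Accounting for a CSV read: accepted + rejected = input rows."""

    n_input: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    n_flagged: int = 0
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_accepted + self.n_rejected != self.n_input:
            raise ValueError("accepted + rejected must equal input rows")
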