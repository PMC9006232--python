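import datetime as dt

import numpy as np
import pandas as pd
import pytest

from cropwatch import CameraStation, DutyCalendar, GeneratorConfig, SpeciesParams


def make_detections(times_by_station: dict[str, list[str]], species: str = "baboon",
                    date: str = "2013-05-01") -> pd.DataFrame:
    """Detection table from 'HH:MM[:SS]' strings per station."""
    rows = []
    for sid, times in times_by_station.items():
        for t in times:
            rows.append((sid, pd.Timestamp(f"{date} {t}"), species))
    frame = pd.DataFrame(rows, columns=["station_id", "timestamp", "species"])
    return frame.sort_values(["timestamp", "station_id"]).reset_index(drop=True)


def make_truth(rows: list[tuple]) -> pd.DataFrame:
    """Truth table from (species, start-iso, duration_min, group, pos, items)."""
    frame = pd.DataFrame(
        rows,
        columns=["species", "start", "duration_min", "group_size", "entry_position_m", "items_removed"],
    )
    frame["start"] = pd.to_datetime(frame["start"])
    frame = frame.sort_values(["start", "species"]).reset_index(drop=True)
    frame.insert(0, "event_id", np.arange(len(frame), dtype="int64"))
    return frame


@pytest.fixture
def one_station() -> list[CameraStation]:
    return [CameraStation("C1", 30.0, 20.0, 40.0)]


@pytest.fixture
def small_config() -> GeneratorConfig:
    """A short, low-rate study for fast constructive tests."""
    return GeneratorConfig(
        start_date=dt.date(2013, 5, 1),
        end_date=dt.date(2013, 5, 20),
        species={
            "baboon": SpeciesParams(daily_rate=2.0, group_size_lambda=4.0),
            "vervet": SpeciesParams(daily_rate=1.5, group_size_lambda=2.0),
        },
        seed=7,
    )


@pytest.fixture
def full_calendar() -> DutyCalendar:
    dates = frozenset(
        dt.date(2013, 5, 1) + dt.timedelta(days=i) for i in range(20)
    )
    return DutyCalendar("researcher", dates)
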