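"""Synthetic crop-foraging data with the structure the analysis assumes.

The generator produces ground-truth incursions by two diurnal primate
species into a 1-ha butternut squash field bordered by a 100 m edge of
natural vegetation, and then degrades that truth into what each of
three methods would actually record:

* a row of motion-triggered cameras on the field edge, shooting
  three-photo bursts with a post-trigger rest period;
* a crop guard who logs incursions with strong species bias (by
  default responding to baboons in 85% of cases but to vervets in only
  15%);
* researchers in a hide who see essentially every incursion on their
  duty days (about five days per week, dawn to dusk) and count the
  crop items each individual carries out.

Ground truth: per species, daily event counts are Poisson with a rate
that varies sinusoidally across ten-day blocks of the season (so that
period means carry real between-period signal); event start times are
uniform over 06:00-18:00; durations are exponential with a mean well
below 30 minutes; entry positions along the field edge are biased away
from the guard station.  Successive same-species events are separated
by at least ``min_event_gap_min`` of empty field.

Each simulated method draws from its own random stream split from the
master seed, so adding or reparameterising one method never perturbs
the draws of another.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    DETECTION_COLUMNS,
    GUARD_COLUMNS,
    RESEARCHER_COLUMNS,
    SPECIES,
    TRUTH_COLUMNS,
    CameraStation,
    DutyCalendar,
    validate_stations,
)

EDGE_LENGTH_M = 100.0

#: Default study window: the overlap period over which all three
#: methods were simultaneously recording (100 days = 10 ten-day periods).
DEFAULT_START = dt.date(2013, 5, 1)
DEFAULT_END = dt.date(2013, 8, 8)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-species foraging and detectability parameters.

    daily_rate: mean incursions/day before seasonal modulation.
    rate_amplitude: relative amplitude of the sinusoidal rate variation
        across ten-day blocks (0 = constant rate).
    group_size_lambda: rate of the zero-truncated Poisson group size.
    duration_mean_min: mean of the exponential event duration (minutes).
    items_per_individual_mean: Poisson mean crop items carried out per
        individual per event.
    guard_detect_prob: probability the guard logs an event.
    camera_trigger_p: per passage-opportunity probability that an
        individual passing a camera triggers it.
    """

    daily_rate: float
    rate_amplitude: float = 0.7
    group_size_lambda: float = 5.0
    duration_mean_min: float = 10.0
    items_per_individual_mean: float = 1.0
    guard_detect_prob: float = 0.5
    camera_trigger_p: float = 0.7

    def __post_init__(self) -> None:
        if self.daily_rate < 0:
            raise ValueError("daily_rate must be >= 0")
        if not 0 <= self.rate_amplitude < 1:
            raise ValueError("rate_amplitude must be in [0, 1)")
        if self.duration_mean_min <= 0:
            raise ValueError("duration_mean_min must be > 0")
        for p in (self.guard_detect_prob, self.camera_trigger_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")


def default_species_params() -> dict[str, SpeciesParams]:
    # Baboons: larger, noisier parties removing more squash; vervets:
    # smaller, harder for guard and cameras to detect.
    return {
        "baboon": SpeciesParams(
            daily_rate=3.0,
            group_size_lambda=8.0,
            items_per_individual_mean=1.5,
            guard_detect_prob=0.85,
            camera_trigger_p=0.9,
        ),
        "vervet": SpeciesParams(
            daily_rate=2.0,
            group_size_lambda=3.0,
            items_per_individual_mean=0.5,
            guard_detect_prob=0.15,
            camera_trigger_p=0.4,
        ),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic study."""

    start_date: dt.date = DEFAULT_START
    end_date: dt.date = DEFAULT_END
    species: dict[str, SpeciesParams] = field(default_factory=default_species_params)
    guard_position_m: float = 0.0
    guard_avoidance_weight: float = 2.0
    guard_log_delay_min: float = 2.0
    researcher_detect_prob: float = 1.0
    researcher_missing_items_frac: float = 0.1
    researcher_duty_days_per_week: int = 5
    burst_size: int = 3
    rest_seconds: float = 5.0
    inter_photo_seconds: float = 1.0
    passage_spread_seconds: float = 60.0
    min_event_gap_min: float = 1.0
    block_len_days: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_date < self.start_date:
            raise ValueError("empty date range")
        if self.burst_size < 1:
            raise ValueError("burst_size must be >= 1")
        for p in (self.researcher_detect_prob, self.researcher_missing_items_frac):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.guard_position_m <= EDGE_LENGTH_M:
            raise ValueError("guard_position_m must lie on the field edge")
        if self.min_event_gap_min < 0:
            raise ValueError("min_event_gap_min must be >= 0")
        for name in self.species:
            if name not in SPECIES:
                raise ValueError(f"unknown species {name!r}")

    @property
    def dates(self) -> list[dt.date]:
        n = (self.end_date - self.start_date).days + 1
        return [self.start_date + dt.timedelta(days=i) for i in range(n)]

    def streams(self) -> dict[str, np.random.Generator]:
        """One independent random stream per simulated component."""
        names = ["truth", "researcher", "guard", "camera", "calendar"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def default_stations() -> list[CameraStation]:
    """Five cameras at 20-m intervals along the 100 m field edge.

    Adjacent views abut so the full edge is covered (camera spacing was
    chosen in the field so no movement between cameras went unrecorded).
    """
    return validate_stations(
        [
            CameraStation(f"C{i + 1}", pos, pos - 10.0, pos + 10.0)
            for i, pos in enumerate((10.0, 30.0, 50.0, 70.0, 90.0))
        ]
    )


def _block_rate(params: SpeciesParams, block: int, n_blocks: int) -> float:
    phase = 2.0 * math.pi * (block + 0.5) / max(n_blocks, 1)
    return params.daily_rate * (1.0 + params.rate_amplitude * math.sin(phase))


def _sample_entry_positions(
    n: int, guard_pos: float, weight: float, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF sample from density proportional to exp(w * d(x)/L)."""
    if n == 0:
        return np.empty(0)
    grid = np.linspace(0.0, EDGE_LENGTH_M, 2001)
    dens = np.exp(weight * np.abs(grid - guard_pos) / EDGE_LENGTH_M)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2.0)])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, grid)


def _sample_group_sizes(
    n: int, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Zero-truncated Poisson via rejection."""
    out = rng.poisson(lam, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.poisson(lam, size=int(zero.sum()))


def empty_truth() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": pd.Series(dtype="int64"),
            "species": pd.Series(dtype=str),
            "start": pd.Series(dtype="datetime64[ns]"),
            "duration_min": pd.Series(dtype=float),
            "group_size": pd.Series(dtype="int64"),
            "entry_position_m": pd.Series(dtype=float),
            "items_removed": pd.Series(dtype="int64"),
        }
    )


def generate_truth(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Ground-truth crop-foraging events over the configured season.

    Daily per-species counts are Poisson before the minimum-gap
    thinning; all starts lie in [06:00, 18:00) and consecutive
    same-species events are separated by at least min_event_gap_min of
    empty field.
    """
    if rng is None:
        rng = config.streams()["truth"]
    dates = config.dates
    n_blocks = max(len(dates) // config.block_len_days, 1)
    gap = dt.timedelta(minutes=config.min_event_gap_min)
    day_seconds = 12 * 3600  # 06:00-18:00
    rows: list[tuple] = []
    for sp in sorted(config.species):
        params = config.species[sp]
        prev_end: dt.datetime | None = None
        for i, date in enumerate(dates):
            block = min(i // config.block_len_days, n_blocks - 1)
            n = rng.poisson(_block_rate(params, block, n_blocks))
            if n == 0:
                continue
            offsets = np.sort(rng.uniform(0, day_seconds, size=n))
            durations = rng.exponential(params.duration_mean_min, size=n)
            groups = _sample_group_sizes(n, params.group_size_lambda, rng)
            positions = _sample_entry_positions(
                n, config.guard_position_m, config.guard_avoidance_weight, rng
            )
            day_start = dt.datetime.combine(date, dt.time(6, 0))
            for off, dur, g, pos in zip(offsets, durations, groups, positions):
                start = day_start + dt.timedelta(seconds=float(round(off)))
                if prev_end is not None and start < prev_end + gap:
                    continue  # field not yet empty: thin the draw
                items = int(rng.poisson(params.items_per_individual_mean, size=g).sum())
                rows.append((sp, start, float(dur), int(g), float(pos), items))
                prev_end = start + dt.timedelta(minutes=float(dur))
    frame = pd.DataFrame(
        rows,
        columns=["species", "start", "duration_min", "group_size", "entry_position_m", "items_removed"],
    )
    if frame.empty:
        return empty_truth()
    frame = frame.sort_values(["start", "species"], kind="stable").reset_index(drop=True)
    frame.insert(0, "event_id", np.arange(len(frame), dtype="int64"))
    return frame.loc[:, TRUTH_COLUMNS]


def make_duty_calendars(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> dict[str, DutyCalendar]:
    """Duty calendars: cameras 24/7, guard daily 06:00-18:00, researchers
    a seeded draw of duty days per week between dawn and dusk."""
    if rng is None:
        rng = config.streams()["calendar"]
    dates = config.dates
    weeks: dict[tuple[int, int], list[dt.date]] = {}
    for d in dates:
        iso = d.isocalendar()
        weeks.setdefault((iso[0], iso[1]), []).append(d)
    res_dates: set[dt.date] = set()
    k = config.researcher_duty_days_per_week
    for _, wdates in sorted(weeks.items()):
        take = min(k, len(wdates))
        idx = rng.choice(len(wdates), size=take, replace=False)
        res_dates.update(wdates[i] for i in sorted(idx))
    all_dates = frozenset(dates)
    return {
        "camera": DutyCalendar(
            "camera", all_dates, dt.time(0, 0), dt.time(23, 59, 59)
        ),
        "guard": DutyCalendar("guard", all_dates),
        "researcher": DutyCalendar("researcher", frozenset(res_dates)),
    }


def simulate_researcher(
    truth: pd.DataFrame,
    calendar: DutyCalendar,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Researcher observations: near-perfect detection on duty days.

    Each truth event on a duty date is observed independently with
    ``researcher_detect_prob``; observed events carry exact entry/exit
    times; a configurable fraction has its crop-item count unrecorded
    (missing, distinct from zero).
    """
    if rng is None:
        rng = config.streams()["researcher"]
    rows = []
    for ev in truth.itertuples():
        start: dt.datetime = ev.start.to_pydatetime()
        if not calendar.on_duty(start.date()):
            continue
        if rng.random() >= config.researcher_detect_prob:
            continue
        end = start + dt.timedelta(minutes=float(ev.duration_min))
        missing = rng.random() < config.researcher_missing_items_frac
        rows.append(
            (
                start.date(),
                start.time(),
                end.time(),
                ev.species,
                pd.NA if missing else int(ev.items_removed),
                int(ev.event_id),
            )
        )
    frame = pd.DataFrame(rows, columns=RESEARCHER_COLUMNS + ["truth_id"])
    frame["items_removed"] = pd.array(frame["items_removed"], dtype="Int64")
    return frame.sort_values(["date", "entry_time"], kind="stable").reset_index(drop=True)


def simulate_guard(
    truth: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Guard log: species-biased incomplete detection of truth events.

    Each event is logged independently with the species' guard
    detection probability; the written time is the event start plus a
    small response delay.  The guard is on duty every day, 06:00-18:00.
    """
    if rng is None:
        rng = config.streams()["guard"]
    delay = dt.timedelta(minutes=config.guard_log_delay_min)
    rows = []
    for ev in truth.itertuples():
        p = config.species[ev.species].guard_detect_prob
        if rng.random() >= p:
            continue
        logged = ev.start.to_pydatetime() + delay
        rows.append((logged.date(), logged.time(), ev.species, int(ev.event_id)))
    frame = pd.DataFrame(rows, columns=GUARD_COLUMNS + ["truth_id"])
    return frame.sort_values(["date", "time"], kind="stable").reset_index(drop=True)


def simulate_cameras(
    truth: pd.DataFrame,
    stations: list[CameraStation],
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Camera photographs of truth events, honoring burst and rest mechanics.

    An event at a given edge position can trigger every station whose
    view interval contains that position.  Trigger opportunities arise
    as individuals pass the camera line: the first individual at the
    event start, further individuals spread shortly after the start,
    and (for groups) again near the event end as animals exit.  Each
    opportunity triggers with the species' per-photo probability; a
    trigger emits a burst of ``burst_size`` photos
    ``inter_photo_seconds`` apart, after which the station cannot
    re-trigger until the rest period has elapsed.
    """
    if not stations:
        raise ValueError("stations must be non-empty")
    validate_stations(stations)
    if rng is None:
        rng = config.streams()["camera"]
    # (station, opportunity second, species, truth_id) candidate triggers
    candidates: dict[str, list[tuple[int, str, int]]] = {s.station_id: [] for s in stations}
    epoch = dt.datetime(2000, 1, 1)
    for ev in truth.itertuples():
        covering = [s for s in stations if s.covers(float(ev.entry_position_m))]
        if not covering:
            continue
        start: dt.datetime = ev.start.to_pydatetime()
        end = start + dt.timedelta(minutes=float(ev.duration_min))
        g = int(ev.group_size)
        times = [0.0]
        if g > 1:
            times.extend(rng.uniform(0, config.passage_spread_seconds, size=g - 1))
        passages = [start + dt.timedelta(seconds=t) for t in times]
        if g > 1:  # exit passages as the group leaves the field
            exits = rng.uniform(0, config.passage_spread_seconds, size=g)
            passages.extend(end - dt.timedelta(seconds=float(t)) for t in exits)
        p = config.species[ev.species].camera_trigger_p
        for t in passages:
            sec = int((t - epoch).total_seconds())
            for s in covering:
                if rng.random() < p:
                    candidates[s.station_id].append((sec, ev.species, int(ev.event_id)))
    # refractory scan per station: emit bursts, suppress triggers during rest
    busy_for = (config.burst_size - 1) * config.inter_photo_seconds + config.rest_seconds
    rows = []
    for sid in sorted(candidates):
        busy_until = -math.inf
        for sec, sp, tid in sorted(candidates[sid]):
            if sec < busy_until:
                continue
            for k in range(config.burst_size):
                ts = epoch + dt.timedelta(seconds=sec + k * config.inter_photo_seconds)
                rows.append((sid, ts, sp, tid))
            busy_until = sec + busy_for
    frame = pd.DataFrame(rows, columns=DETECTION_COLUMNS + ["truth_id"])
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame.sort_values(["timestamp", "station_id"], kind="stable").reset_index(drop=True)


@dataclass
class SimulatedData:
    """One complete synthetic study: truth plus all three methods' records."""

    config: GeneratorConfig
    stations: list[CameraStation]
    calendars: dict[str, DutyCalendar]
    truth: pd.DataFrame
    detections: pd.DataFrame
    guard: pd.DataFrame
    researcher: pd.DataFrame


def simulate_dataset(
    config: GeneratorConfig, stations: list[CameraStation] | None = None
) -> SimulatedData:
    """Run the full generator: truth and all three observation methods."""
    if stations is None:
        stations = default_stations()
    streams = config.streams()
    truth = generate_truth(config, streams["truth"])
    calendars = make_duty_calendars(config, streams["calendar"])
    return SimulatedData(
        config=config,
        stations=stations,
        calendars=calendars,
        truth=truth,
        detections=simulate_cameras(truth, stations, config, streams["camera"]),
        guard=simulate_guard(truth, config, streams["guard"]),
        researcher=simulate_researcher(truth, calendars["researcher"], config, streams["researcher"]),
    )
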