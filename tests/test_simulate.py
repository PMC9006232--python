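"""Generator behavior: constructive constraints, marginal distributions,
seed determinism, burst/rest mechanics and guard-avoidance bias."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cropwatch import (
    CameraStation,
    DutyCalendar,
    GeneratorConfig,
    SpeciesParams,
    generate_truth,
    make_duty_calendars,
    simulate_cameras,
    simulate_dataset,
    simulate_guard,
    simulate_researcher,
)
from cropwatch.simulate import empty_truth

from conftest import make_truth


def _config(**kw) -> GeneratorConfig:
    base = dict(
        start_date=dt.date(2013, 5, 1),
        end_date=dt.date(2013, 8, 8),
        seed=11,
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestGenerateTruth:
    def test_zero_rates_give_empty_table(self):
        cfg = _config(
            species={
                "baboon": SpeciesParams(daily_rate=0.0),
                "vervet": SpeciesParams(daily_rate=0.0),
            }
        )
        assert generate_truth(cfg).empty

    def test_total_count_within_poisson_interval(self):
        # constant rate 3/day over 100 days; short durations keep the
        # minimum-gap thinning negligible, so the total should sit in
        # the central 99% interval of Poisson(300)
        cfg = _config(
            species={
                "baboon": SpeciesParams(
                    daily_rate=3.0, rate_amplitude=0.0, duration_mean_min=2.0
                )
            },
            seed=5,
        )
        n = len(generate_truth(cfg))
        lo, hi = stats.poisson.ppf([0.005, 0.995], 300)
        assert lo <= n <= hi

    def test_min_gap_between_same_species_events(self):
        cfg = _config(seed=3)
        truth = generate_truth(cfg)
        gap = pd.Timedelta(minutes=cfg.min_event_gap_min)
        for _, grp in truth.groupby("species"):
            grp = grp.sort_values("start")
            ends = grp["start"] + pd.to_timedelta(grp["duration_min"], unit="m")
            assert (grp["start"].iloc[1:].to_numpy() - ends.iloc[:-1].to_numpy()
                    >= gap.to_timedelta64()).all()

    def test_starts_within_diurnal_window(self):
        truth = generate_truth(_config(seed=2))
        tod = truth["start"].dt.time
        assert (tod >= dt.time(6, 0)).all() and (tod < dt.time(18, 0)).all()

    def test_empty_date_range_rejected(self):
        with pytest.raises(ValueError, match="date range"):
            _config(start_date=dt.date(2013, 5, 2), end_date=dt.date(2013, 5, 1))

    def test_guard_avoidance_shifts_entries_away_from_guard(self):
        far = generate_truth(_config(guard_avoidance_weight=3.0, seed=9))
        uniform = generate_truth(_config(guard_avoidance_weight=0.0, seed=9))
        g = 0.0  # guard at the southerly corner
        assert (far["entry_position_m"] - g).abs().mean() > (
            uniform["entry_position_m"] - g
        ).abs().mean()


class TestResearcher:
    def test_perfect_observer_reproduces_truth_on_duty_dates(self, full_calendar):
        truth = make_truth(
            [
                ("baboon", "2013-05-01 08:00:00", 20.0, 5, 50.0, 7),
                ("vervet", "2013-05-02 10:00:00", 10.0, 2, 80.0, 1),
                ("baboon", "2013-06-15 09:00:00", 15.0, 4, 20.0, 3),  # off-duty
            ]
        )
        cfg = _config(researcher_detect_prob=1.0, researcher_missing_items_frac=0.0)
        obs = simulate_researcher(truth, full_calendar, cfg)
        assert len(obs) == 2
        assert list(obs["items_removed"]) == [7, 1]
        assert obs.loc[0, "exit_time"] == dt.time(8, 20)

    def test_detect_prob_zero_observes_nothing(self, full_calendar):
        truth = make_truth([("baboon", "2013-05-01 08:00:00", 20.0, 5, 50.0, 7)])
        cfg = _config(researcher_detect_prob=0.0)
        assert simulate_researcher(truth, full_calendar, cfg).empty

    def test_missing_items_fraction_within_binomial_interval(self, full_calendar):
        n = 1000
        rows = []
        base = pd.Timestamp("2013-05-01 06:00:00")
        for i in range(n):
            rows.append(("baboon", base + pd.Timedelta(minutes=10 * i), 2.0, 3, 50.0, 4))
        truth = make_truth([(sp, s.isoformat(), d, g, p, it) for sp, s, d, g, p, it in rows])
        cal = DutyCalendar(
            "researcher",
            frozenset(dt.date(2013, 5, 1) + dt.timedelta(days=i) for i in range(30)),
        )
        cfg = _config(researcher_missing_items_frac=0.2, seed=13)
        obs = simulate_researcher(truth, cal, cfg)
        missing = int(obs["items_removed"].isna().sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], len(obs), 0.2)
        assert lo <= missing <= hi


class TestGuard:
    def test_degenerate_probabilities_select_exactly_one_species(self):
        truth = make_truth(
            [
                ("baboon", "2013-05-01 08:00:00", 20.0, 5, 50.0, 7),
                ("vervet", "2013-05-01 10:00:00", 10.0, 2, 80.0, 1),
                ("baboon", "2013-05-02 09:00:00", 15.0, 4, 20.0, 3),
            ]
        )
        cfg = _config(
            species={
                "baboon": SpeciesParams(daily_rate=1, guard_detect_prob=1.0),
                "vervet": SpeciesParams(daily_rate=1, guard_detect_prob=0.0),
            }
        )
        log = simulate_guard(truth, cfg)
        assert len(log) == 2 and set(log["species"]) == {"baboon"}

    def test_empty_truth_gives_empty_log(self):
        assert simulate_guard(empty_truth(), _config()).empty

    def test_species_biased_detection_fractions(self):
        # >= 1000 events per species; detected fractions must land in
        # the central 99% binomial intervals around 0.85 and 0.15
        rows = []
        base = pd.Timestamp("2013-05-01 06:00:00")
        for i in range(1200):
            rows.append(("baboon", (base + pd.Timedelta(minutes=7 * i)).isoformat(), 2.0, 5, 50.0, 4))
            rows.append(("vervet", (base + pd.Timedelta(minutes=7 * i, seconds=200)).isoformat(), 2.0, 2, 70.0, 1))
        truth = make_truth(rows)
        cfg = _config(seed=21)
        log = simulate_guard(truth, cfg)
        for sp, p in (("baboon", 0.85), ("vervet", 0.15)):
            k = int((log["species"] == sp).sum())
            lo, hi = stats.binom.ppf([0.005, 0.995], 1200, p)
            assert lo <= k <= hi, f"{sp}: {k} outside [{lo}, {hi}]"

    def test_logged_time_carries_configured_delay(self):
        truth = make_truth([("baboon", "2013-05-01 08:00:00", 20.0, 5, 50.0, 7)])
        cfg = _config(
            guard_log_delay_min=2.0,
            species={"baboon": SpeciesParams(daily_rate=1, guard_detect_prob=1.0)},
        )
        log = simulate_guard(truth, cfg)
        assert log.loc[0, "time"] == dt.time(8, 2)


class TestCameras:
    STATIONS = [
        CameraStation("C1", 30.0, 20.0, 40.0),
        CameraStation("C2", 70.0, 60.0, 80.0),
    ]

    def test_empty_truth_no_detections(self):
        cfg = _config()
        assert simulate_cameras(empty_truth(), self.STATIONS, cfg).empty

    def test_single_animal_triggers_one_burst_on_covering_station(self):
        truth = make_truth([("baboon", "2013-05-01 08:00:00", 10.0, 1, 30.0, 2)])
        cfg = _config(
            species={"baboon": SpeciesParams(daily_rate=1, camera_trigger_p=1.0)}
        )
        det = simulate_cameras(truth, self.STATIONS, cfg)
        assert len(det) == 3  # one three-shot burst
        assert set(det["station_id"]) == {"C1"}
        gaps = det["timestamp"].diff().dropna()
        assert (gaps == pd.Timedelta(seconds=1)).all()
        assert det["timestamp"].iloc[0] == pd.Timestamp("2013-05-01 08:00:00")

    def test_rest_period_suppresses_rapid_retriggers(self):
        # two animals' passages within 2 s: only one burst may fire,
        # and burst starts must always be >= rest_seconds apart
        truth = make_truth(
            [("baboon", "2013-05-01 08:00:00", 0.05, 2, 30.0, 0)]
        )
        cfg = _config(
            species={"baboon": SpeciesParams(daily_rate=1, camera_trigger_p=1.0)},
            passage_spread_seconds=2.0,
            seed=17,
        )
        det = simulate_cameras(truth, self.STATIONS, cfg)
        # four passage opportunities all inside the busy window: one burst
        assert len(det) == 3
        assert det["timestamp"].iloc[0] == pd.Timestamp("2013-05-01 08:00:00")

    def test_inter_burst_start_gap_at_least_rest_for_any_seed(self):
        for seed in range(5):
            cfg = _config(seed=seed)
            data = simulate_dataset(cfg)
            det = data.detections
            for sid, grp in det.groupby("station_id"):
                ts = grp["timestamp"].sort_values().to_numpy()
                # burst starts: photos not preceded within inter_photo gap
                diffs = np.diff(ts) / np.timedelta64(1, "s")
                burst_start = np.concatenate([[True], diffs > cfg.inter_photo_seconds])
                starts = ts[burst_start]
                if len(starts) > 1:
                    gaps = np.diff(starts) / np.timedelta64(1, "s")
                    assert (gaps >= cfg.rest_seconds).all()

    def test_every_detection_maps_to_one_truth_event(self):
        cfg = _config(seed=23)
        data = simulate_dataset(cfg)
        truth_ids = set(data.truth["event_id"])
        for table in (data.detections, data.guard, data.researcher):
            assert set(table["truth_id"]).issubset(truth_ids)

    def test_uncovered_position_never_photographed(self):
        truth = make_truth([("baboon", "2013-05-01 08:00:00", 10.0, 3, 50.0, 2)])
        cfg = _config(
            species={"baboon": SpeciesParams(daily_rate=1, camera_trigger_p=1.0)}
        )
        det = simulate_cameras(truth, self.STATIONS, cfg)  # 50 m not in view
        assert det.empty


def test_seed_determinism_across_all_outputs():
    cfg = _config(seed=31)
    a, b = simulate_dataset(cfg), simulate_dataset(cfg)
    pd.testing.assert_frame_equal(a.truth, b.truth)
    pd.testing.assert_frame_equal(a.detections, b.detections)
    pd.testing.assert_frame_equal(a.guard, b.guard)
    pd.testing.assert_frame_equal(a.researcher, b.researcher)
    assert a.calendars["researcher"].dates == b.calendars["researcher"].dates


def test_duty_calendars_respect_days_per_week():
    cfg = _config(researcher_duty_days_per_week=5)
    cals = make_duty_calendars(cfg)
    assert len(cals["guard"].dates) == len(cfg.dates)
    assert len(cals["camera"].dates) == len(cfg.dates)
    by_week = {}
    for d in cals["researcher"].dates:
        by_week.setdefault(d.isocalendar()[:2], []).append(d)
    assert all(len(v) <= 5 for v in by_week.values())
    # full interior weeks have exactly five duty days
    full_weeks = [w for w, days in by_week.items() if len(days) == 5]
    assert full_weeks
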