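"""End-to-end pipeline: data in, events, period measures, agreement
table and camera-subset simulation out, with a provenance manifest.

One structured YAML config drives both modes:

* ``mode: synthetic`` — a generator block simulates truth and the three
  methods' records, which are written out and then analysed exactly as
  real data would be;
* ``mode: real`` — paths to camera/guard/researcher CSVs and a stations
  file, plus duty calendars (``all`` days of the analysis window, an
  explicit date list, or ``from_data`` to use the dates present in a
  method's file).

All stage I/O goes through files; re-running with the same config and
seed reproduces byte-identical stage outputs (the manifest's wall-clock
timestamps aside).
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .agreement import MethodAgreement, fits_to_frame
from .events import (
    cluster_detections,
    daily_event_counts,
    guard_records_to_events,
    researcher_records_to_events,
)
from .io import (
    read_camera_csv,
    read_guard_csv,
    read_researcher_csv,
    read_stations_csv,
    write_detections_csv,
    write_events_csv,
    write_guard_csv,
    write_researcher_csv,
    write_stations_csv,
)
from .periods import aggregate_to_periods, build_periods, crop_loss_daily, matched_days
from .simulate import GeneratorConfig, SpeciesParams, simulate_dataset
from .subsets import subset_event_counts, subset_summary
from .types import ClusteringConfig, DutyCalendar

logger = logging.getLogger(__name__)


def _parse_date(v) -> dt.date:
    return v if isinstance(v, dt.date) else dt.date.fromisoformat(str(v))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "mode" not in cfg:
        raise ValueError("config must be a mapping with a 'mode' key")
    if cfg["mode"] not in ("synthetic", "real"):
        raise ValueError(f"unknown mode {cfg['mode']!r}")
    return cfg


def generator_config_from_dict(block: dict, seed: int) -> GeneratorConfig:
    species = {
        name: SpeciesParams(**params)
        for name, params in (block.get("species") or {}).items()
    }
    kwargs = {k: v for k, v in block.items() if k != "species"}
    for key in ("start_date", "end_date"):
        if key in kwargs:
            kwargs[key] = _parse_date(kwargs[key])
    if species:
        kwargs["species"] = species
    return GeneratorConfig(seed=seed, **kwargs)


def _calendar_from_spec(
    method: str, spec, window_dates: list[dt.date], data_dates: set[dt.date]
) -> DutyCalendar:
    if spec in (None, "all"):
        dates = frozenset(window_dates)
    elif spec == "from_data":
        logger.warning(
            "%s duty calendar derived from data dates; duty days with zero "
            "events will look like absences",
            method,
        )
        dates = frozenset(data_dates)
    elif isinstance(spec, list):
        dates = frozenset(_parse_date(d) for d in spec)
    else:
        raise ValueError(f"calendar spec for {method} must be 'all', 'from_data' or a date list")
    window = (dt.time(0, 0), dt.time(23, 59, 59)) if method == "camera" else (
        dt.time(6, 0),
        dt.time(18, 0),
    )
    return DutyCalendar(method, dates, *window)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Run every stage and return the output directory.

    Writes: truth.csv (synthetic mode), camera_photos.csv,
    guard_log.csv, researcher_log.csv, stations.csv, events.csv,
    period_measures.csv, agreement_table.csv, agreement_summary.txt,
    subsets.csv, subset_summary.csv, resolved_config.yaml, manifest.json.
    """
    cfg = load_config(config_path)
    out = Path(out_dir or cfg.get("output_dir", "cropwatch_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    counts: dict[str, int] = {}

    analysis = cfg.get("analysis", {})
    clustering = ClusteringConfig(**cfg.get("clustering", {}))

    # --- stage 1: acquire data -------------------------------------------
    if cfg["mode"] == "synthetic":
        gen = generator_config_from_dict(cfg.get("synthetic", {}), seed)
        data = simulate_dataset(gen)
        stations, calendars = data.stations, data.calendars
        detections, guard, researcher = data.detections, data.guard, data.researcher
        data.truth.to_csv(out / "truth.csv", index=False)
        write_detections_csv(detections, out / "camera_photos.csv")
        write_guard_csv(guard, out / "guard_log.csv")
        write_researcher_csv(researcher, out / "researcher_log.csv")
        write_stations_csv(stations, out / "stations.csv")
        a_start = _parse_date(analysis.get("start_date", gen.start_date))
        a_end = _parse_date(analysis.get("end_date", gen.end_date))
        counts["truth_events"] = len(data.truth)
    else:
        real = cfg.get("real", {})
        for key in ("camera_photos", "guard_log", "researcher_log", "stations"):
            if key not in real:
                raise ValueError(f"real mode config missing {key!r}")
        stations = read_stations_csv(real["stations"])
        strict = bool(cfg.get("strict", False))
        detections, rep_c = read_camera_csv(real["camera_photos"], stations, strict)
        guard, rep_g = read_guard_csv(real["guard_log"], strict=strict)
        researcher, rep_r = read_researcher_csv(real["researcher_log"], strict)
        counts["camera_rows_rejected"] = rep_c.n_rejected
        counts["guard_rows_rejected"] = rep_g.n_rejected
        counts["researcher_rows_rejected"] = rep_r.n_rejected
        if "start_date" not in analysis or "end_date" not in analysis:
            raise ValueError("real mode requires analysis.start_date and end_date")
        a_start, a_end = _parse_date(analysis["start_date"]), _parse_date(analysis["end_date"])
        window_dates = [
            a_start + dt.timedelta(days=i) for i in range((a_end - a_start).days + 1)
        ]
        cal_spec = cfg.get("calendars", {})
        calendars = {
            "camera": _calendar_from_spec(
                "camera", cal_spec.get("camera"), window_dates,
                set(pd.to_datetime(detections["timestamp"]).dt.date) if not detections.empty else set(),
            ),
            "guard": _calendar_from_spec(
                "guard", cal_spec.get("guard"), window_dates, set(guard["date"])
            ),
            "researcher": _calendar_from_spec(
                "researcher",
                cal_spec.get("researcher", "from_data"),
                window_dates,
                set(researcher["date"]),
            ),
        }
    counts["camera_photos"] = len(detections)
    counts["guard_records"] = len(guard)
    counts["researcher_records"] = len(researcher)

    # --- stage 2: event delineation --------------------------------------
    camera_events = cluster_detections(detections, clustering)
    guard_events = guard_records_to_events(guard, clustering)
    researcher_events = researcher_records_to_events(researcher, clustering)
    events = pd.concat(
        [camera_events, guard_events, researcher_events], ignore_index=True
    )
    write_events_csv(events, out / "events.csv")
    counts["camera_events"] = len(camera_events)
    counts["guard_events"] = len(guard_events)
    counts["researcher_events"] = len(researcher_events)

    # --- stage 3: matched-day period aggregation --------------------------
    window_dates = [a_start + dt.timedelta(days=i) for i in range((a_end - a_start).days + 1)]
    window_set = set(window_dates)
    restricted = {
        m: DutyCalendar(m, frozenset(set(c.dates) & window_set), c.window_start, c.window_end)
        for m, c in calendars.items()
    }

    def _in_window(ev: pd.DataFrame) -> pd.DataFrame:
        if ev.empty:
            return ev
        d = pd.to_datetime(ev["start"]).dt.date
        return ev[d.isin(window_set)]

    daily = {
        ("camera", "events_per_day"): daily_event_counts(
            _in_window(camera_events), restricted["camera"]
        ),
        ("guard", "events_per_day"): daily_event_counts(
            _in_window(guard_events), restricted["guard"]
        ),
        ("researcher", "events_per_day"): daily_event_counts(
            _in_window(researcher_events), restricted["researcher"]
        ),
        ("researcher", "items_per_day"): crop_loss_daily(
            _in_window(researcher_events), restricted["researcher"]
        ),
    }
    matched = matched_days(restricted)
    periods = build_periods(a_start, a_end, int(analysis.get("period_len_days", 10)))
    measures = aggregate_to_periods(daily, matched, periods)
    measures.to_csv(out / "period_measures.csv", index=False)
    counts["period_measures"] = len(measures)

    # --- stage 4: agreement regressions ----------------------------------
    results = MethodAgreement(measures).fit()
    fits_to_frame(results.fits).to_csv(out / "agreement_table.csv", index=False)
    (out / "agreement_summary.txt").write_text(results.summary() + "\n")
    counts["agreement_fits"] = len(results.fits)

    # --- stage 5: camera-subset simulation --------------------------------
    sizes = set(cfg.get("subsets", {}).get("sizes", range(1, len(stations) + 1)))
    # subsets run over the full camera deployment stream by default
    subset_detections = detections
    if cfg.get("subsets", {}).get("restrict_to_analysis_window", False):
        d = pd.to_datetime(detections["timestamp"]).dt.date
        subset_detections = detections[d.isin(window_set)]
    subs = subset_event_counts(subset_detections, stations, sizes, clustering)
    subs.to_csv(out / "subsets.csv", index=False)
    summary = subset_summary(subs)
    summary["by_size"].to_csv(out / "subset_summary.csv", index=False)
    summary["fold_ratio"].to_csv(out / "subset_fold_ratio.csv", index=False)
    counts["subset_rows"] = len(subs)

    # --- provenance --------------------------------------------------------
    resolved = dict(cfg)
    resolved["seed"] = seed
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "row_counts": counts,
        "output_checksums": {
            p.name: _sha256(p) for p in sorted(out.glob("*.csv"))
        },
        "created": dt.datetime.now().isoformat(timespec="seconds"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
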