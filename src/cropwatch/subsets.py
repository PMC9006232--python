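"""Camera-subset design simulation.

How many cameras does a field-edge survey need?  For every combination
of the deployed camera stations (all subsets of sizes 1-4, plus the
full set), the photo stream is restricted to the subset's stations and
the 30-minute independence rule is re-applied, yielding the number of
independent crop-foraging events that subset *would have recorded*.

Pooling more stations adds photos monotonically, but the event count
need not grow: an extra station's photo can bridge two otherwise
separate events into one.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .events import cluster_detections
from .types import CameraStation, ClusteringConfig, SPECIES


def enumerate_subsets(
    stations: list[CameraStation] | list[str], sizes: set[int]
) -> list[tuple[str, ...]]:
    """All station-id combinations of the requested sizes, lexicographic."""
    ids = sorted(s.station_id if isinstance(s, CameraStation) else s for s in stations)
    if any(k < 1 or k > len(ids) for k in sizes):
        raise ValueError(f"subset sizes must lie in 1..{len(ids)}")
    out: list[tuple[str, ...]] = []
    for k in sorted(sizes):
        out.extend(combinations(ids, k))
    return out


def subset_event_counts(
    detections: pd.DataFrame,
    stations: list[CameraStation],
    sizes: set[int],
    config: ClusteringConfig = ClusteringConfig(),
) -> pd.DataFrame:
    """Independent event counts per station subset and species.

    For each subset the detections are restricted to its stations and
    re-clustered with the same independence window used by the main
    pipeline; the full set (when its size is requested) reproduces the
    main pipeline's counts exactly.
    """
    results = []
    for subset in enumerate_subsets(stations, sizes):
        events = cluster_detections(detections, config, stations_subset=set(subset))
        counts = events.groupby("species").size() if not events.empty else pd.Series(dtype=int)
        for sp in sorted(SPECIES):
            results.append(
                ("+".join(subset), len(subset), sp, int(counts.get(sp, 0)))
            )
    return pd.DataFrame(
        results, columns=["station_ids", "subset_size", "species", "n_events"]
    )


def subset_summary(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries of one subset run.

    Returns per-size min/median/max event counts per species, the
    single-camera table (the per-station-alone counts mapped in the
    field), and the per-species fold ratio between the best and worst
    single camera (flagged undefined when the minimum is zero).
    """
    by_size = (
        results.groupby(["species", "subset_size"])["n_events"]
        .agg(["min", "median", "max"])
        .reset_index()
    )
    singles = results[results["subset_size"] == 1].rename(
        columns={"station_ids": "station_id"}
    )[["station_id", "species", "n_events"]]
    folds = []
    for sp, grp in singles.groupby("species"):
        lo, hi = int(grp["n_events"].min()), int(grp["n_events"].max())
        folds.append(
            (sp, hi, lo, hi / lo if lo > 0 else np.nan, lo == 0)
        )
    fold = pd.DataFrame(
        folds, columns=["species", "max_count", "min_count", "fold_ratio", "undefined"]
    )
    return {"by_size": by_size, "single_camera": singles, "fold_ratio": fold}
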