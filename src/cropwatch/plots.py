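"""Plots for the camera-subset design simulation."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .types import SPECIES


def plot_counts_vs_subset_size(
    results: pd.DataFrame, path: str | Path, show_combinations: bool = True
) -> None:
    """Independent event count against number of cameras, per species.

    With ``show_combinations`` every individual subset is a point
    (jittered by rank); otherwise per-size min/median/max whiskers are
    drawn.  Both renderings of the same run are legitimate.
    """
    fig, axes = plt.subplots(1, len(SPECIES), figsize=(10, 4), sharey=False)
    for ax, sp in zip(axes, sorted(SPECIES)):
        sub = results[results["species"] == sp]
        if show_combinations:
            ax.scatter(sub["subset_size"], sub["n_events"], s=14, alpha=0.6)
        else:
            agg = sub.groupby("subset_size")["n_events"].agg(["min", "median", "max"])
            ax.errorbar(
                agg.index,
                agg["median"],
                yerr=[agg["median"] - agg["min"], agg["max"] - agg["median"]],
                fmt="o",
            )
        ax.set_xlabel("number of cameras")
        ax.set_ylabel("independent crop-foraging events")
        ax.set_title(sp)
        ax.set_xticks(sorted(sub["subset_size"].unique()))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_single_camera_counts(
    singles: pd.DataFrame,
    positions: dict[str, float],
    path: str | Path,
    guard_position_m: float | None = None,
) -> None:
    """Events recorded by each camera alone, by position on the field edge."""
    fig, axes = plt.subplots(1, len(SPECIES), figsize=(10, 4))
    for ax, sp in zip(axes, sorted(SPECIES)):
        sub = singles[singles["species"] == sp].copy()
        sub["position_m"] = sub["station_id"].map(positions)
        sub = sub.sort_values("position_m")
        ax.bar(sub["position_m"], sub["n_events"], width=6.0)
        if guard_position_m is not None:
            ax.axvline(guard_position_m, color="red", linestyle="--", label="guard")
            ax.legend()
        ax.set_xlabel("position on field edge (m)")
        ax.set_ylabel("events recorded alone")
        ax.set_title(sp)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
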