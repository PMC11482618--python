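"""Matplotlib figures mirroring the standard night-activity reports."""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .metrics import TimeBudget
from .sway import SwayTrace

__all__ = ["plot_time_budgets", "plot_cumulative_curves", "plot_sway_trace"]


def plot_time_budgets(budgets: Mapping[str, TimeBudget], ax=None):
    """Grouped bar chart of time budgets, one group per method/night."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    keys = list(budgets)
    labels = list(next(iter(budgets.values())).percents.index)
    width = 0.8 / len(keys)
    xs = np.arange(len(labels))
    for i, key in enumerate(keys):
        ax.bar(xs + i * width, budgets[key].percents.reindex(labels).to_numpy(),
               width=width, label=key)
    ax.set_xticks(xs + 0.4 - width / 2)
    ax.set_xticklabels(labels, rotation=30, ha="right")
    ax.set_ylabel("% of observation time")
    ax.legend()
    return ax


def plot_cumulative_curves(curves: pd.DataFrame, ax=None):
    """Cumulative seconds per behavior over the night."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    minutes = np.arange(len(curves)) / 60.0
    for col in curves.columns:
        ax.plot(minutes, curves[col].to_numpy(), label=col)
    ax.set_xlabel("minutes since start of observation")
    ax.set_ylabel("cumulative seconds")
    ax.legend()
    return ax


def plot_sway_trace(trace: SwayTrace, sway_seconds: np.ndarray | None = None,
                    ax=None):
    """Cumulative trunk displacement, optionally against scored sway time.

    ``sway_seconds`` is an optional boolean/0-1 per-second series of
    manually scored sway; it is drawn cumulatively on a second y-axis so
    steep displacement increases can be compared with scored bouts.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    minutes = np.arange(len(trace.cumulative)) / trace.fps / 60.0
    ax.plot(minutes, trace.cumulative, color="tab:red",
            label=f"cumulative {trace.bodypart} movement")
    ax.set_xlabel("minutes since start of observation")
    ax.set_ylabel("cumulative pixel movement", color="tab:red")
    for start, end in trace.bouts:
        ax.axvspan(start / 60.0, end / 60.0, alpha=0.15, color="tab:orange")
    if sway_seconds is not None:
        ax2 = ax.twinx()
        mins = np.arange(len(sway_seconds)) / 60.0
        ax2.plot(mins, np.cumsum(np.asarray(sway_seconds, dtype=float)),
                 color="tab:purple", label="scored sway (cumulative s)")
        ax2.set_ylabel("cumulative scored sway (s)", color="tab:purple")
    return ax
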