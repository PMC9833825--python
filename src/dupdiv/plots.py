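"""Minimal static summary figures.

Only two plots are provided: the YFP-vs-CFP population scatter coloured by
day (the standard view of adaptive dynamics in this system, with the
amplification diagonal for orientation) and a single-sample event scatter.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import Thresholds

__all__ = ["plot_population_scatter", "plot_event_scatter"]


def plot_population_scatter(table: pd.DataFrame, thresholds: Thresholds | None = None, ax=None):
    """Scatter of per-population (yfp_norm, cfp_norm), shaded by day.

    ``table`` needs columns (day, yfp_norm, cfp_norm).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        table["cfp_norm"], table["yfp_norm"], c=table["day"], cmap="Greys", s=15,
        edgecolors="k", linewidths=0.2,
    )
    lim = max(1.0, table[["yfp_norm", "cfp_norm"]].to_numpy().max()) * 1.2
    diag = np.linspace(0.5, lim, 10)
    ax.plot(diag, diag, ls="--", lw=0.8, color="tab:blue", label="amplification diagonal")
    if thresholds is not None:
        ax.axhline(thresholds.theta_y, ls=":", lw=0.8, color="grey")
        ax.axvline(thresholds.theta_c, ls=":", lw=0.8, color="grey")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("normalized CFP (copy-number proxy)")
    ax.set_ylabel("normalized YFP (expression proxy)")
    ax.legend(frameon=False, fontsize=8)
    plt.colorbar(sc, ax=ax, label="day")
    return ax


def plot_event_scatter(events: pd.DataFrame, ax=None):
    """Log-log single-cell YFP/CFP scatter of one event table."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(events["cfp"], events["yfp"], s=3, alpha=0.3, color="k")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("CFP fluorescence")
    ax.set_ylabel("YFP fluorescence")
    return ax
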