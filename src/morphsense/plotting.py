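"""Auxiliary plots: threshold scatter with the identity diagonal, group curve."""

from __future__ import annotations

import pandas as pd


def threshold_scatter(thresholds: pd.DataFrame, ax=None):
    """Scatter of per-participant thresholds, condition A (x) vs B (y).

    Points above the diagonal mean greater sensitivity in the y-axis
    condition.  ``thresholds`` is the participants x conditions frame from
    the group report (two columns).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x_label, y_label = thresholds.columns[1], thresholds.columns[0]
    ax.scatter(thresholds[x_label], thresholds[y_label], marker="s", color="k")
    lo = min(thresholds.min().min(), 60.0)
    ax.plot([lo, 100], [lo, 100], ls="--", c="grey", lw=1)
    ax.set_xlabel(f"{x_label} threshold (% dilution)")
    ax.set_ylabel(f"{y_label} threshold (% dilution)")
    ax.set_aspect("equal")
    return ax


def group_curve_plot(curve: pd.DataFrame, ax=None):
    """Mean +/- SEM percent correct vs dilution, one line per condition."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for cond, sub in curve.groupby("condition"):
        ax.errorbar(
            sub["dilution_pct"], sub["mean_pct"], yerr=sub["sem_pct"],
            marker="o", capsize=2, label=str(cond),
        )
    ax.set_xlabel("stimulus dilution (%)")
    ax.set_ylabel("percent correct")
    ax.set_ylim(45, 102)
    ax.legend()
    return ax
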