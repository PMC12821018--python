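"""Minimal plotting helpers: per-map elasticity heatmaps and binned series."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_map", "plot_binned_series"]


def plot_map(emap, ax=None, cmap="viridis"):
    """Scatter heatmap of K over map positions (QC-passing entries only)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    kept = emap.retained()
    sc = ax.scatter(kept["x_um"], kept["y_um"], c=kept["K_Pa"], cmap=cmap,
                    marker="s", s=60)
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label="K (Pa)")
    return ax


def plot_binned_series(binned, ax=None, **kwargs):
    """Mean +/- SD time series from a binned-series table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    b = binned[~binned["underflow"]]
    ax.errorbar(b["bin_start_h"] + 0.5, b["mean"],
                yerr=np.where(np.isnan(b["sd"]), 0.0, b["sd"]),
                fmt="o-", capsize=3, **kwargs)
    ax.set_xlabel("time postmortem (h)")
    return ax
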