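"""Matplotlib figures for the agreement analysis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .evaluation import EvalConfig, bland_altman
from .grids import VFGrid

__all__ = ["bland_altman_plot", "pointwise_mae_heatmap"]


def bland_altman_plot(est, act, cfg: EvalConfig = EvalConfig(), ax=None):
    """Difference-vs-mean scatter with bias and 95% limits of agreement."""
    est = np.asarray(est, dtype=float)
    act = np.asarray(act, dtype=float)
    stats_ = bland_altman(est, act, cfg)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((est + act) / 2, est - act, s=12, alpha=0.6)
    for key, style in (("bias", "-"), ("loa_low", "--"), ("loa_high", "--")):
        ax.axhline(stats_[key], linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of estimated and actual MD (dB)")
    ax.set_ylabel("estimated − actual MD (dB)")
    return ax


def pointwise_mae_heatmap(mae_map: dict, grid: VFGrid, ax=None):
    """Per-point MAE drawn at the grid coordinates (OD frame)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xy = grid.xy()
    idx = sorted(mae_map)
    vals = [mae_map[i] for i in idx]
    sc = ax.scatter(xy[idx, 0], xy[idx, 1], c=vals, s=180, cmap="Blues",
                    edgecolors="k", linewidths=0.4)
    for i, v in zip(idx, vals):
        ax.annotate(f"{v:.1f}", xy[i], ha="center", va="center", fontsize=6)
    ax.set_xlabel("x (deg, temporal > 0)")
    ax.set_ylabel("y (deg, superior > 0)")
    ax.set_aspect("equal")
    plt.colorbar(sc, ax=ax, label="MAE (dB)")
    return ax
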