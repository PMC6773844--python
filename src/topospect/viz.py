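"""Minimal topographic map export: channel positions coloured by a
statistic, significant channels ringed in white."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .layout import SensorLayout


def plot_topomap(layout: SensorLayout, values: np.ndarray,
                 path: str | Path, significant=None,
                 title: str | None = None, cmap: str = "RdYlBu_r") -> None:
    """Scatter the sensors in top-down projection, coloured by ``values``;
    writes PNG or SVG depending on the path suffix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = layout.positions[:, :2]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    vmax = float(np.abs(values).max() or 1.0)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=values, cmap=cmap,
                    vmin=-vmax, vmax=vmax, s=60)
    if significant is not None:
        sig = np.asarray(significant, bool)
        ax.scatter(xy[sig, 0], xy[sig, 1], facecolors="none",
                   edgecolors="white", linewidths=1.6, s=90)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.8)
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
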