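"""Small plotting helpers for radar and APS views."""

from __future__ import annotations

import numpy as np

from .radar import PositionGateSet, RadarLayout


def radar_scatter(points: np.ndarray, labels=None, layout: RadarLayout = None,
                  gates: PositionGateSet = None, ax=None, s: float = 2.0):
    """Scatter of events in radar space, optionally with axis spokes and
    position-gate outlines. Returns the matplotlib Axes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    points = np.asarray(points)
    if labels is None:
        ax.scatter(points[:, 0], points[:, 1], s=s, alpha=0.4)
    else:
        labels = np.asarray(labels, dtype=object)
        for lab in sorted(set(labels)):
            sel = labels == lab
            ax.scatter(points[sel, 0], points[sel, 1], s=s, alpha=0.4,
                       label=str(lab))
        ax.legend(markerscale=4, fontsize=8)
    if layout is not None:
        scale = 0.9 * float(np.abs(points).max() or 1.0)
        for axis in layout.axes:
            dx = scale * axis.weight * np.cos(axis.angle)
            dy = scale * axis.weight * np.sin(axis.angle)
            ax.annotate("", xy=(dx, dy), xytext=(0, 0),
                        arrowprops=dict(arrowstyle="->", color="gray"))
            ax.text(dx, dy, axis.marker, fontsize=8, color="gray")
    if gates is not None:
        for label, poly in sorted(gates.gates.items()):
            x, y = poly.exterior.xy
            ax.plot(x, y, lw=1, color="black")
            cx, cy = poly.centroid.coords[0]
            ax.text(cx, cy, str(label), fontsize=10, ha="center")
        x, y = gates.normal_region.exterior.xy
        ax.plot(x, y, lw=1, ls="--", color="green")
    ax.set_xlabel("radar x")
    ax.set_ylabel("radar y")
    return ax
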