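"""Optional scatter plot of the importance-satisfaction matrix."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .indices import ItemResult, MatrixOrigin


def plot_matrix(
    results: Sequence[ItemResult],
    origin: MatrixOrigin,
    path: str | Path,
) -> None:
    """Save the (|DSI|, SI) scatter with origin cross-hairs (SVG/PNG)."""
    fig, ax = plt.subplots(figsize=(6, 6))
    xs = [abs(r.dsi) for r in results]
    ys = [r.si for r in results]
    ax.scatter(xs, ys, s=25, color="tab:blue", zorder=3)
    for r, x, y in zip(results, xs, ys):
        ax.annotate(r.item_id, (x, y), textcoords="offset points", xytext=(4, 4),
                    fontsize=8)
    ax.axvline(origin.x0, color="grey", lw=1)
    ax.axhline(origin.y0, color="grey", lw=1)
    ax.set_xlabel("|DSI| (importance)")
    ax.set_ylabel("SI (satisfaction)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title("Importance-satisfaction matrix")
    for name, (qx, qy) in {
        "I predominance": (0.97, 0.97),
        "II improving": (0.03, 0.97),
        "III secondary improving": (0.03, 0.03),
        "IV reserving": (0.97, 0.03),
    }.items():
        ax.text(qx, qy, name, transform=ax.transAxes, fontsize=8, color="grey",
                ha="right" if qx > 0.5 else "left",
                va="top" if qy > 0.5 else "bottom")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
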