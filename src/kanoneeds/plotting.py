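"""Quadrant scatter plot of better/worse coefficients."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kano import Centroid, KanoCoefficients

_QUADRANT_NOTES = {
    # (high |DSI|?, high SI?) -> annotation, axes-relative position
    "O": ("one-dimensional (O)", (0.97, 0.97)),
    "A": ("attractive (A)", (0.03, 0.97)),
    "I": ("indifferent (I)", (0.03, 0.03)),
    "M": ("must-be (M)", (0.97, 0.03)),
}


def quadrant_scatter(
    coeffs: Sequence[KanoCoefficients],
    centroid: Centroid,
    path: str | Path,
) -> Path:
    """Scatter of the needs with SI on the y-axis and |DSI| on the x-axis,
    crosshairs at the centroid, one labelled point per need."""
    fig, ax = plt.subplots(figsize=(6.5, 6))
    xs = [abs(c.dsi) for c in coeffs]
    ys = [c.si for c in coeffs]
    ax.scatter(xs, ys, color="tab:blue", zorder=3)
    for c, x, y in zip(coeffs, xs, ys):
        ax.annotate(c.need_id, (x, y), textcoords="offset points", xytext=(5, 4), fontsize=9)
    ax.axvline(centroid.mean_abs_dsi, color="grey", lw=1)
    ax.axhline(centroid.mean_si, color="grey", lw=1)
    ax.plot(centroid.mean_abs_dsi, centroid.mean_si, "k+", markersize=10, zorder=4)
    ax.annotate(
        f"centroid ({centroid.mean_si:.3f}, {centroid.mean_abs_dsi:.3f})",
        (centroid.mean_abs_dsi, centroid.mean_si),
        textcoords="offset points",
        xytext=(6, -12),
        fontsize=8,
        color="dimgrey",
    )
    for label, (x, y) in _QUADRANT_NOTES.values():
        ax.text(x, y, label, transform=ax.transAxes, fontsize=9, color="dimgrey",
                ha="right" if x > 0.5 else "left", va="top" if y > 0.5 else "bottom")
    ax.set_xlabel("|DSI| (worse coefficient magnitude)")
    ax.set_ylabel("SI (better coefficient)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title("Better-worse quadrant classification")
    fig.tight_layout()
    out = Path(path)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
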