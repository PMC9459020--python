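"""Headless snapshot rendering of an epithelium or simulation state.

Fate color code: founders (R8-like) dark purple; the three photoreceptor
waves in progressively paler pink; border cells green; precursors drawn as
outlines only.  An unfinished furrow appears as a dashed vertical line.

Figures use a full-bleed axes whose data limits equal the domain, so data
coordinates map linearly onto image pixels (convenient for pixel checks).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import EllipseCollection

from .epithelium import Epithelium, Fate
from .furrow import SimulationState

#: fate -> fill color (hex); precursors get no fill
FATE_COLORS = {
    Fate.R8: "#4b0082",
    Fate.PR_WAVE1: "#c2185b",
    Fate.PR_WAVE2: "#e57fb1",
    Fate.PR_WAVE3: "#f4c2dc",
    Fate.BORDER: "#2e8b57",
}
PRECURSOR_EDGE = "#999999"
FURROW_COLOR = "#333333"
DPI = 100


def render_snapshot(state, path, fmt: str | None = None, width_px: int = 800):
    """Draw every cell as a filled circle and save a PNG or SVG.

    ``state`` may be a :class:`SimulationState` or a bare epithelium.
    Returns the (width, height) of the produced figure in pixels.
    """
    ep: Epithelium = state.ep if isinstance(state, SimulationState) else state
    furrow = state.furrow if isinstance(state, SimulationState) else None
    dom = ep.domain
    aspect = dom.height / dom.width if dom.width > 0 else 1.0
    w_in = width_px / DPI
    fig = plt.figure(figsize=(w_in, w_in * aspect), dpi=DPI)
    ax = fig.add_axes((0.0, 0.0, 1.0, 1.0))
    ax.set_xlim(dom.xmin, dom.xmax)
    ax.set_ylim(dom.ymin, dom.ymax)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.add_patch(
        plt.Rectangle(
            (dom.xmin, dom.ymin), dom.width, dom.height,
            facecolor="white", edgecolor="black", linewidth=1.0, zorder=0,
        )
    )
    rows = ep.alive_rows()
    if len(rows):
        fates = ep.fate[rows]
        # draw precursors first so specified cells sit on top
        for fate_val, face, edge, z in [(int(Fate.PRECURSOR), "none", PRECURSOR_EDGE, 1)] + [
            (int(f), FATE_COLORS[f], FATE_COLORS[f], 2) for f in FATE_COLORS
        ]:
            sel = rows[fates == fate_val]
            if not len(sel):
                continue
            diam = 2.0 * ep.radius[sel]
            coll = EllipseCollection(
                diam, diam, np.zeros(len(sel)), units="xy",
                offsets=ep.pos[sel], offset_transform=ax.transData,
                facecolors=face, edgecolors=edge, linewidths=0.5, zorder=z,
            )
            ax.add_collection(coll)
    if furrow is not None and not furrow.finished and dom.xmin <= furrow.x <= dom.xmax:
        ax.axvline(furrow.x, linestyle="--", color=FURROW_COLOR, linewidth=1.2, zorder=3)
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower() if "." in str(path) else "png"
    if fmt not in ("png", "svg"):
        raise ValueError(f"unsupported format {fmt!r}; use png or svg")
    fig.savefig(path, format=fmt, dpi=DPI)
    size = fig.get_size_inches() * DPI
    plt.close(fig)
    return int(round(size[0])), int(round(size[1]))


def data_to_pixel(ep: Epithelium, xy, width_px: int = 800) -> tuple[int, int]:
    """Map world coordinates to pixel indices (row, col) of a saved PNG.

    Valid because the snapshot axes are full-bleed with data limits equal to
    the domain; pixel row 0 is the top of the image."""
    dom = ep.domain
    aspect = dom.height / dom.width if dom.width > 0 else 1.0
    h_px = int(round(width_px * aspect))
    col = int((xy[0] - dom.xmin) / dom.width * width_px)
    row = int(h_px - 1 - (xy[1] - dom.ymin) / dom.height * h_px)
    return row, col
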