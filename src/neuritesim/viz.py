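"""Snapshot rendering (diagnostic, not figure-quality).

Draws the closed membrane outline, the nuclear outline, the actin
filaments, and the head beads.  SVG output is deterministic: rendering
the same state twice yields identical bytes (fixed hash salt, no
timestamp metadata), which lets tests parse the vector output back.
"""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Polygon as MplPolygon

from .model import BondKind, CellState, Role


def render_snapshot(state: CellState, path: str | Path, dpi: int = 150) -> None:
    """Render one cell state to a raster (.png) or vector (.svg) file."""
    path = Path(path)
    from .morphometrics import membrane_ring_order  # local import: avoids cycle

    with plt.rc_context({"svg.hashsalt": "neuritesim"}):
        fig, ax = plt.subplots(figsize=(6, 6))
        mem = state.positions[membrane_ring_order(state)]
        ax.add_patch(MplPolygon(mem, closed=True, fill=False,
                                edgecolor="tab:blue", lw=1.5,
                                label="membrane", gid="membrane"))
        nuc_ids = state.nuclear_indices
        if len(nuc_ids) >= 3:
            # nuclear ring order: same id-ordering trick as the membrane
            nuc = state.positions[nuc_ids]
            ax.add_patch(MplPolygon(nuc, closed=True, fill=False,
                                    edgecolor="tab:purple", lw=1.0,
                                    label="nucleus", gid="nucleus"))
        fil_ids = np.unique(state.filament_ids[state.filament_ids >= 0])
        for f in fil_ids:
            members = np.flatnonzero(state.filament_ids == f)
            pts = state.positions[members]
            ax.plot(pts[:, 0], pts[:, 1], color="tab:red", lw=0.8)
        heads = state.indices_of(Role.ACTIN_HEAD)
        if len(heads):
            ax.plot(state.positions[heads, 0], state.positions[heads, 1],
                    "o", ms=3, color="tab:orange")
        ax.set_aspect("equal")
        ax.set_title(f"t = {state.time:.4g}")
        extent = np.abs(state.positions).max() * 1.1
        ax.set_xlim(-extent, extent)
        ax.set_ylim(-extent, extent)
        if path.suffix.lower() == ".svg":
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path, dpi=dpi)
        plt.close(fig)
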