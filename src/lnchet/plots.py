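"""Plotting helpers (matplotlib, Agg-safe).

Only the SOM portrait renderer lives here; everything else in the pipeline
writes tables, and figures are an optional extra.
"""

from __future__ import annotations

import math

import numpy as np

from .som import SOMGrid, _ROW_H


def plot_portrait(grid: SOMGrid, values: np.ndarray, path: str, title: str = "") -> None:
    """Render one SOM component (per-unit values) as a hexagon lattice image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PatchCollection
    from matplotlib.patches import RegularPolygon

    pos = grid.positions()
    patches = [
        RegularPolygon((x, y), numVertices=6, radius=1.0 / math.sqrt(3.0),
                       orientation=0.0)
        for x, y in pos
    ]
    fig, ax = plt.subplots(figsize=(grid.xdim / 3.0 + 1, grid.ydim * _ROW_H / 3.0 + 1))
    coll = PatchCollection(patches, cmap="RdBu_r")
    finite = np.isfinite(values)
    vmax = np.nanmax(np.abs(values)) if finite.any() else 1.0
    coll.set_array(np.where(finite, values, 0.0))
    coll.set_clim(-vmax, vmax)
    ax.add_collection(coll)
    ax.set_xlim(-1, grid.xdim + 1)
    ax.set_ylim(-1, grid.ydim * _ROW_H + 1)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.colorbar(coll, ax=ax, shrink=0.7)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
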