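"""Adjacency-matrix heatmaps with diverging excitatory/inhibitory scale."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .graphs import RolledCFC

__all__ = ["plot_adjacency"]


def plot_adjacency(
    graph: RolledCFC | pd.DataFrame | np.ndarray,
    path: str | Path,
    labels: Sequence[str] | None = None,
    mask_diagonal: bool = False,
    title: str | None = None,
) -> Path:
    """Render a square weighted adjacency matrix as a heatmap.

    Positive weights (excitatory) map to blue, negative (inhibitory) to red,
    on a symmetric diverging scale.  ``mask_diagonal`` greys out
    self-connections regardless of their values.  Returns the written path.
    """
    if isinstance(graph, RolledCFC):
        adj = graph.to_adjacency()
        labels = adj.index
        mat = adj.to_numpy()
    elif isinstance(graph, pd.DataFrame):
        labels = labels if labels is not None else graph.index
        mat = graph.to_numpy(dtype=float)
    else:
        mat = np.asarray(graph, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("adjacency must be square")
    n = mat.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]

    display = np.ma.masked_invalid(mat)
    if mask_diagonal:
        display = np.ma.masked_where(np.eye(n, dtype=bool), display)
    vmax = float(np.max(np.abs(display))) if display.count() else 0.0
    vmax = vmax or 1.0

    fig, ax = plt.subplots(figsize=(max(4, n * 0.25), max(3.5, n * 0.25)))
    cmap = plt.get_cmap("RdBu").copy()
    cmap.set_bad(color="0.85")
    im = ax.imshow(display, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xlabel("target region")
    ax.set_ylabel("source region")
    if n <= 40:
        ax.set_xticks(range(n), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(n), labels, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="edge weight")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
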