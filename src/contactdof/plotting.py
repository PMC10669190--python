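"""Figure-level plotting hooks: contact heat maps, stacked secondary-
structure bars, and embedding scatter plots."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .secstruct import STATES

_SS_COLORS = {
    "H": "#d62728", "G": "#ff9896", "I": "#e377c2",
    "E": "#1f77b4", "B": "#aec7e8",
    "T": "#2ca02c", "S": "#ffdd57", "-": "#d9d9d9",
}


def contact_heatmap(mean_map: np.ndarray, ax: Optional[plt.Axes] = None,
                    title: str = ""):
    """Ensemble-mean contact map as a heat map over internal indices."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    n = mean_map.shape[0]
    im = ax.imshow(mean_map, origin="lower", vmin=0, vmax=1, cmap="viridis",
                   extent=(0.5, n + 0.5, 0.5, n + 0.5))
    ax.set_xlabel("internal index")
    ax.set_ylabel("internal index")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label="contact probability")
    return ax


def stacked_ss_bars(fractions: pd.DataFrame, ax: Optional[plt.Axes] = None,
                    title: str = ""):
    """Stacked per-residue bars of the 8-state fractions."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    bottom = np.zeros(len(fractions))
    for state in STATES:
        vals = fractions[state].to_numpy()
        ax.bar(fractions.index, vals, bottom=bottom,
               color=_SS_COLORS[state], width=0.85,
               label=state if state != "-" else "none")
        bottom += vals
    ax.set_xlabel("internal index")
    ax.set_ylabel("state fraction")
    ax.set_ylim(0, 1)
    ax.set_title(title)
    ax.legend(ncol=4, fontsize=7, loc="upper right")
    return ax


def embedding_scatter(results: dict, ax: Optional[plt.Axes] = None,
                      title: str = ""):
    """Overlay per-system projections sharing one coordinate system."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    for name, res in results.items():
        xy = res.coordinates
        ax.scatter(xy[:, 0], xy[:, 1] if xy.shape[1] > 1 else np.zeros(len(xy)),
                   s=4, alpha=0.5, label=name)
    ax.set_xlabel("collective DOF 1")
    ax.set_ylabel("collective DOF 2")
    ax.set_title(title)
    ax.legend(fontsize=7)
    return ax
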