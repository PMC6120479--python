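"""Matrix heatmap in the screen's colour convention (green = increase,
red = decrease relative to same-field wild-type)."""

from __future__ import annotations

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .depmatrix import matrix_pivot


def plot_matrix(matrix: pd.DataFrame, compartment: str = "end1",
                ax: "plt.Axes | None" = None, vmax: float = 1.0):
    """Heatmap of relative differences for one compartment; entries not
    called significant are masked to white."""
    wide = matrix_pivot(matrix, compartment, "rel_diff")
    calls = matrix_pivot(matrix, compartment, "call")
    data = wide.to_numpy(dtype=float)
    data[(calls == "ns").to_numpy()] = np.nan
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    cmap = matplotlib.colormaps["RdYlGn"].copy()
    cmap.set_bad("white")
    im = ax.imshow(data, cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(wide.shape[1]),
                  [f"{d}Δ" for d in wide.columns], rotation=45,
                  ha="right")
    ax.set_yticks(range(wide.shape[0]), list(wide.index))
    ax.set_xlabel("deletion")
    ax.set_ylabel("GFP marker")
    ax.set_title(f"relative difference vs wild-type ({compartment})")
    plt.colorbar(im, ax=ax, label="rel_diff")
    return ax
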