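"""Heat-map rendering of grid maps.

Each map is drawn with its own min-max colour scale (the colour bar spans
the lowest to the highest value of that map); ostium squares are black.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .mapping import CohortAverageMap, GridMap


def render_map_png(grid: GridMap | CohortAverageMap, path: str | Path, title: str | None = None) -> None:
    if isinstance(grid, CohortAverageMap):
        grid = grid.as_grid_map()
    values = np.ma.masked_invalid(grid.values)
    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("viridis").copy()
    cmap.set_bad("black")
    im = ax.imshow(values, cmap=cmap, vmin=values.min(), vmax=values.max())
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title or f"{grid.metric} ({grid.units})", fontsize=9)
    ax.set_ylabel("flow → downstream")
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)


def render_correlation_grid(table, path: str | Path) -> None:
    """Matrix-style figure of median r per metric pair (rows x columns),
    annotated with significance."""
    import pandas as pd

    df = pd.DataFrame(table)
    metrics = sorted(set(df["metric_a"]) | set(df["metric_b"]))
    n = len(metrics)
    mat = np.full((n, n), np.nan)
    sig = np.zeros((n, n), dtype=bool)
    for _, row in df.iterrows():
        i, j = metrics.index(row["metric_a"]), metrics.index(row["metric_b"])
        mat[i, j] = mat[j, i] = row["median_r"]
        sig[i, j] = sig[j, i] = bool(row["significant"])
    fig, ax = plt.subplots(figsize=(1.2 * n, 1.2 * n))
    im = ax.imshow(np.ma.masked_invalid(mat), cmap="coolwarm", vmin=-1, vmax=1)
    ax.set_xticks(range(n), metrics, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(n), metrics, fontsize=7)
    for i in range(n):
        for j in range(n):
            if np.isfinite(mat[i, j]):
                label = f"{mat[i, j]:.2f}" + ("" if sig[i, j] else "\nNS")
                ax.text(j, i, label, ha="center", va="center", fontsize=6)
    fig.colorbar(im, ax=ax, fraction=0.046)
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
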