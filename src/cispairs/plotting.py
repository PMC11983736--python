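"""Optional figure output: per-stratum scatter plots and a clustered heatmap.

matplotlib is imported lazily so the core pipeline has no hard dependency
on it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import Dendrogram
from .containers import ExpressionMatrix

__all__ = ["stratum_scatter_plots", "heatmap"]


def _pyplot():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def stratum_scatter_plots(
    cells: pd.DataFrame, out_dir, gene_names: tuple[str, str] = ("gene A", "gene B")
) -> list[Path]:
    """One scatter-with-regression-line panel per (cell type, exposure) stratum.

    Returns the written file paths; the global (all cells) panel is always
    included.
    """
    plt = _pyplot()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = [("ALL", "ALL", cells)]
    for (ct, ex), sub in cells.groupby(["cell_type", "exposure"], observed=True):
        groups.append((str(ct), str(ex), sub))
    written = []
    for ct, ex, sub in groups:
        fig, ax = plt.subplots(figsize=(4, 4))
        x = sub["value_a"].to_numpy()
        y = sub["value_b"].to_numpy()
        ax.scatter(x, y, s=4, alpha=0.3, linewidths=0)
        if len(sub) >= 3 and x.std() > 0:
            slope, intercept = np.polyfit(x, y, 1)
            grid = np.linspace(x.min(), x.max(), 50)
            ax.plot(grid, slope * grid + intercept, color="firebrick", lw=1.5)
        ax.set_xlabel(gene_names[0])
        ax.set_ylabel(gene_names[1])
        ax.set_title(f"{ct} / {ex} (n={len(sub)})")
        path = out_dir / f"scatter_{ct}_{ex}.png".replace(" ", "_")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


def heatmap(matrix: ExpressionMatrix, dendrogram: Dendrogram, path) -> Path:
    """log2-intensity heatmap with features in dendrogram leaf order."""
    plt = _pyplot()
    ordered = matrix.values.loc[dendrogram.leaf_order]
    log2 = np.log2(np.maximum(ordered.to_numpy(), np.finfo(float).tiny))
    fig, ax = plt.subplots(figsize=(4, max(3, 0.18 * len(ordered))))
    im = ax.imshow(log2, aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(matrix.n_samples), matrix.sample_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(ordered)), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2 intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
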