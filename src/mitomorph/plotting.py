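"""Clustergram heatmaps and per-metric boxplots (matplotlib, headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .phenotype_analysis import Clustergram


def plot_clustergram(cg: Clustergram, path=None, cmap: str = "RdBu_r"):
    """Heatmap of the z-matrix in dendrogram order with flanking trees."""
    fig = plt.figure(figsize=(2 + 0.45 * len(cg.col_labels),
                              2 + 0.3 * len(cg.row_labels)))
    gs = fig.add_gridspec(2, 2, width_ratios=(1, 4), height_ratios=(1, 4),
                          wspace=0.02, hspace=0.02)
    ax_col = fig.add_subplot(gs[0, 1])
    hierarchy.dendrogram(cg.col_linkage, ax=ax_col, no_labels=True,
                         color_threshold=0, above_threshold_color="k")
    ax_col.axis("off")
    ax_row = fig.add_subplot(gs[1, 0])
    hierarchy.dendrogram(cg.row_linkage, ax=ax_row, orientation="left",
                         no_labels=True, color_threshold=0,
                         above_threshold_color="k")
    ax_row.axis("off")
    ax = fig.add_subplot(gs[1, 1])
    ordered = cg.z_matrix[np.ix_(cg.row_order[::-1], cg.col_order)]
    vmax = np.abs(cg.z_matrix).max()
    im = ax.imshow(ordered, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(cg.col_order)))
    ax.set_xticklabels([cg.col_labels[i] for i in cg.col_order], rotation=90)
    ax.set_yticks(range(len(cg.row_order)))
    ax.set_yticklabels([cg.row_labels[i] for i in cg.row_order[::-1]])
    ax.yaxis.tick_right()
    fig.colorbar(im, ax=ax, shrink=0.6, label="z-score")
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
        return None
    return fig


def plot_metric_boxplots(table: pd.DataFrame, metrics, path=None,
                         control_label: str | None = None):
    """One boxplot panel per metric, grouped by condition."""
    conditions = list(table["Condition"].unique())
    if control_label and control_label in conditions:
        conditions = [control_label] + [c for c in conditions if c != control_label]
    ncol = min(4, len(metrics))
    nrow = int(np.ceil(len(metrics) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.6 * nrow),
                             squeeze=False)
    for ax, metric in zip(axes.ravel(), metrics):
        data = [table.loc[table["Condition"] == c, metric].dropna()
                for c in conditions]
        ax.boxplot(data, tick_labels=conditions)
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=45)
    for ax in axes.ravel()[len(metrics):]:
        ax.axis("off")
    fig.tight_layout()
    if path:
        fig.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(fig)
        return None
    return fig
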