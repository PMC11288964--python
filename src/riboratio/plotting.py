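"""Basic diagnostic plots: PCA score plot with ellipses, volcano, heatmap.

These are quick-look figures, not publication graphics; they exist so a
pipeline run can be eyeballed without extra code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .clustering import Dendrogram  # noqa: E402
from .differential import DiffTable  # noqa: E402
from .multivariate import Ellipse, PCAResult  # noqa: E402

__all__ = ["plot_pca", "plot_volcano", "plot_heatmap"]


def plot_pca(
    pca: PCAResult,
    groups: pd.Series | None = None,
    ellipses: list[Ellipse] | None = None,
    path=None,
):
    """Scatter of samples on PC1/PC2, colored by group, with ellipses."""
    fig, ax = plt.subplots(figsize=(5, 4))
    xy = pca.scores.iloc[:, :2]
    if groups is not None:
        for g in pd.unique(groups.reindex(xy.index)):
            pts = xy[groups.reindex(xy.index) == g]
            ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], label=str(g), s=18)
        ax.legend(fontsize=7)
    else:
        ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1], s=18)
    for ell in ellipses or []:
        ring = ell.boundary()
        ax.plot(ring[:, 0], ring[:, 1], lw=1, alpha=0.7)
    ev = pca.explained_var
    ax.set_xlabel(f"PC1 ({ev[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({ev[1] * 100:.1f}%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_volcano(diff: DiffTable, path=None):
    """log2 fold change vs -log10 adjusted p, colored by direction call."""
    fig, ax = plt.subplots(figsize=(5, 4))
    t = diff.table
    with np.errstate(divide="ignore"):
        y = -np.log10(t["p_adj"].to_numpy(dtype=float))
    colors = {"up": "tab:red", "down": "tab:blue", "ns": "0.7", "": "0.9"}
    for call, color in colors.items():
        m = (t["direction"] == call).to_numpy()
        if m.any():
            ax.scatter(t["log2fc"][m], y[m], s=12, c=color,
                       label=call or "untested")
    ax.axhline(-np.log10(diff.alpha), ls="--", lw=0.8, c="0.4")
    ax.set_xlabel(f"log2 FC ({diff.group_a} / {diff.group_b})")
    ax.set_ylabel("-log10 adjusted p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_heatmap(
    scaled: pd.DataFrame,
    row_dend: Dendrogram | None = None,
    col_dend: Dendrogram | None = None,
    path=None,
):
    """Scaled-matrix heatmap with rows/columns in dendrogram leaf order."""
    frame = scaled
    if row_dend is not None:
        frame = frame.loc[row_dend.leaf_order]
    if col_dend is not None:
        frame = frame[col_dend.leaf_order]
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(frame.to_numpy(dtype=float), aspect="auto",
                   cmap="RdBu_r", interpolation="nearest")
    fig.colorbar(im, ax=ax, shrink=0.6, label="row z-score")
    ax.set_xticks(range(frame.shape[1]))
    ax.set_xticklabels(frame.columns, rotation=90, fontsize=5)
    ax.set_yticks([])
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
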