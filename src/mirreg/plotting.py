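"""Minimal figure helpers: correlation heatmap and PCA scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt
import pandas as pd


def correlation_heatmap(corr: pd.DataFrame, leaf_order: list[str] | None = None,
                        path: str | None = None):
    """Heatmap of a sample correlation matrix, optionally in dendrogram order."""
    if leaf_order is not None:
        corr = corr.loc[leaf_order, leaf_order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="Spearman rho")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def pca_scatter(scores: pd.DataFrame, groups: pd.Series | None = None,
                path: str | None = None):
    """PC1/PC2 scatter, coloured by an optional per-sample grouping."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if groups is None:
        ax.scatter(scores["PC1"], scores["PC2"], s=12)
    else:
        for name, idx in groups.groupby(groups).groups.items():
            sub = scores.loc[[i for i in idx if i in scores.index]]
            ax.scatter(sub["PC1"], sub["PC2"], s=12, label=str(name))
        ax.legend(fontsize=8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
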