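"""Minimal plotting helpers: correlation heatmap and PCA biplot.

Matplotlib is imported lazily so the rest of the package works headless
without it.
"""

from __future__ import annotations

import numpy as np

from .stats import CorrelationMatrix, PCAResult

__all__ = ["correlation_heatmap", "pca_biplot"]


def correlation_heatmap(cm: CorrelationMatrix, ax=None):
    """Heatmap of Pearson r with crosses over non-significant pairs."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    traits = list(cm.r.columns)
    im = ax.imshow(cm.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(traits)), traits, rotation=45, ha="right")
    ax.set_yticks(range(len(traits)), traits)
    for i in range(len(traits)):
        for j in range(len(traits)):
            if not bool(cm.significant.iloc[i, j]):
                ax.text(j, i, "x", ha="center", va="center", color="grey")
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax


def pca_biplot(pr: PCAResult, ax=None):
    """Trait loadings on the first two dimensions as arrows."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    if pr.loadings.shape[1] < 2:
        raise ValueError("biplot needs at least two dimensions")
    for trait in pr.loadings.index:
        x, y = pr.loadings.loc[trait, ["dim1", "dim2"]]
        ax.annotate("", xy=(x, y), xytext=(0, 0), arrowprops={"arrowstyle": "->"})
        ax.text(x * 1.07, y * 1.07, trait, ha="center", va="center", fontsize=8)
    lim = float(np.abs(pr.loadings[["dim1", "dim2"]].to_numpy()).max()) * 1.3
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"dim1 ({pr.explained_pct[0]:.1f}%)")
    ax.set_ylabel(f"dim2 ({pr.explained_pct[1]:.1f}%)")
    return ax
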