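"""Basic figure output: association-matrix heatmaps and 2-D PCA scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["association_heatmap", "pca_scatter"]


def association_heatmap(fdr: pd.DataFrame, path, vmax: float = 1.0) -> None:
    """Heatmap of a subclass-mapping FDR matrix (low FDR = light)."""
    fig, ax = plt.subplots(figsize=(1.2 * fdr.shape[1] + 2, 1.0 * fdr.shape[0] + 2))
    im = ax.imshow(fdr.to_numpy(), cmap="gray", vmin=0.0, vmax=vmax)
    ax.set_xticks(range(fdr.shape[1]), fdr.columns, rotation=45, ha="right")
    ax.set_yticks(range(fdr.shape[0]), fdr.index)
    for i in range(fdr.shape[0]):
        for j in range(fdr.shape[1]):
            v = fdr.iloc[i, j]
            ax.text(j, i, f"{v:.3f}", ha="center", va="center",
                    color="white" if v < 0.5 * vmax else "black", fontsize=8)
    fig.colorbar(im, ax=ax, label="FDR")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(embedding: pd.DataFrame, labels: dict, path) -> None:
    """Scatter of the first two principal components, colored by label."""
    fig, ax = plt.subplots(figsize=(6, 5))
    groups = sorted({labels[s] for s in embedding.index})
    for g in groups:
        pts = embedding.loc[[s for s in embedding.index if labels[s] == g]]
        ax.scatter(pts["PC1"], pts["PC2"], s=18, label=g, alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
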