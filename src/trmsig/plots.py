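"""Optional figures: PCA scatter and sample dendrogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram

from .expression import ClusterTree, PcaSummary, SampleDesign


def plot_pca(summary: PcaSummary, design: SampleDesign, path) -> None:
    """PC1 vs PC2 scatter, coloured by condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for condition, group in design.table.groupby("condition"):
        idx = group.index
        ax.scatter(
            summary.scores.loc[idx, "PC1"],
            summary.scores.loc[idx, "PC2"],
            label=condition,
        )
    vf = summary.variance_fraction
    ax.set_xlabel(f"PC1 ({100 * vf[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * vf[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dendrogram(tree: ClusterTree, path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    dendrogram(tree.merges, labels=list(tree.sample_ids), ax=ax, leaf_rotation=90)
    ax.set_ylabel(f"{tree.linkage_name} height ({tree.distance_name} distance)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
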