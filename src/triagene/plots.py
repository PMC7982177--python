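"""Basic figures for the pipeline's stage outputs (PNG via matplotlib Agg)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def mds_bubble_plot(embedding: pd.DataFrame, path: str | Path) -> None:
    """Bubble plot of the enrichment MDS embedding: position by MDS1/MDS2,
    colour by cluster, size by -log10 p, representatives annotated."""
    fig, ax = plt.subplots(figsize=(6, 5))
    size = 30 + 120 * -np.log10(np.clip(embedding["P"], 1e-12, 1))
    ax.scatter(embedding["MDS1"], embedding["MDS2"], s=size,
               c=embedding["CLUSTER"], cmap="tab10", alpha=0.7)
    for _, row in embedding[embedding["REPRESENTATIVE"]].iterrows():
        ax.annotate(row["SET"], (row["MDS1"], row["MDS2"]), fontsize=8)
    ax.set_xlabel("MDS1")
    ax.set_ylabel("MDS2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def comparative_bar_plot(table: pd.DataFrame, path: str | Path) -> None:
    """Grouped bars of real- vs null-trait replication rates per cut point."""
    fig, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(table))
    ax.bar(x - 0.2, table["RATE_REAL"], width=0.4, label="real trait")
    ax.bar(x + 0.2, table["RATE_NULL"], width=0.4, label="null trait")
    ax.set_xticks(x)
    ax.set_xticklabels([f"t{int(t)}@{c}" for t, c in
                        zip(table["TABLE"], table["CUT_POINT"])], fontsize=8)
    ax.set_ylabel("replication rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def dge_boxplot(expr: pd.DataFrame, groups: np.ndarray, genes: list[str],
                path: str | Path) -> None:
    """Side-by-side case/control boxplots for a panel of genes."""
    fig, axes = plt.subplots(1, max(1, len(genes)),
                             figsize=(2.2 * max(1, len(genes)), 3.2),
                             squeeze=False)
    for ax, gene in zip(axes[0], genes):
        vals = expr.loc[gene]
        ax.boxplot([vals[groups == "control"], vals[groups == "case"]],
                   tick_labels=["control", "case"])
        ax.set_title(gene, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
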