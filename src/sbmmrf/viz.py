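"""Basic diagnostic plots: community-ordered heatmap, BIC scree, ARI boxplots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def community_heatmap(adjacency: np.ndarray, z: np.ndarray, path: str | Path,
                      title: str | None = None) -> None:
    """Plot the adjacency matrix with taxa ordered by community label.

    Dashed lines partition the heatmap into community blocks; dense dark
    diagonal blocks indicate high intra-community edge probability.
    """
    z = np.asarray(z)
    order = np.argsort(z, kind="stable")
    A = np.asarray(adjacency)[np.ix_(order, order)]
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(1 - A, cmap="gray", interpolation="nearest")
    boundaries = np.flatnonzero(np.diff(z[order])) + 0.5
    for b in boundaries:
        ax.axhline(b, color="red", linestyle="--", linewidth=0.8)
        ax.axvline(b, color="red", linestyle="--", linewidth=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scree_plot(table: pd.DataFrame, path: str | Path) -> None:
    """BIC versus K; the elbow (or minimum) guides the choice of K."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(table["K"], table["bic"], marker="o")
    ax.set_xlabel("number of communities K")
    ax.set_ylabel("BIC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ari_boxplots(records: pd.DataFrame, path: str | Path,
                 group: str = "method") -> None:
    """Boxplots of ARI by method/setting from a long-format record table."""
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = sorted(records[group].unique())
    data = [records.loc[records[group] == g, "ari"] for g in groups]
    ax.boxplot(data, tick_labels=[str(g) for g in groups])
    ax.set_ylabel("ARI(truth, estimate)")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
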