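"""Optional figures: enrichment bar grid, PCA scatter, expression heatmap."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .structure import SampleEmbedding

__all__ = ["enrichment_bars", "pca_scatter", "heatmap"]


def enrichment_bars(grid: pd.DataFrame, path: str | Path, direction: str = "both") -> None:
    """Ratio bars per motif/length/threshold; control motifs gray, observed
    DE counts annotated, bars shown only with >= 2 DE repeat genes."""
    sub = grid[(grid["direction"] == direction) & grid["displayable"]].copy()
    sub = sub.sort_values(["family", "unit", "k", "fc_threshold"], kind="mergesort")
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(sub)), 4))
    colors = np.where(sub["family"] == "ctg_cag", "#c0392b", "#9e9e9e")
    x = np.arange(len(sub))
    ax.bar(x, sub["ratio"], color=colors)
    for xi, (_, row) in zip(x, sub.iterrows()):
        ax.text(xi, row["ratio"], str(int(row["n_de_repeat"])), ha="center",
                va="bottom", fontsize=7)
    ax.axhline(1.0, color="black", lw=0.8, ls="--")
    ax.set_xticks(x)
    ax.set_xticklabels(
        [f"{r.unit} k{int(r.k)} fc{r.fc_threshold:g}" for r in sub.itertuples()],
        rotation=90, fontsize=7,
    )
    ax.set_ylabel("observed / expected DE repeat genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(emb: SampleEmbedding, condition: pd.Series, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, color in (("control", "#2c7fb8"), ("case", "#d7301f")):
        mask = condition.reindex(emb.coords.index) == cond
        ax.scatter(emb.coords.loc[mask, "PC1"], emb.coords.loc[mask, "PC2"],
                   label=cond, s=25, color=color)
    evr = emb.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0]:.0%})")
    ax.set_ylabel(f"PC2 ({evr[1]:.0%})")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def heatmap(ordered: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5, interpolation="nearest")
    ax.set_xlabel("samples (UPGMA order)")
    ax.set_ylabel("genes (UPGMA order)")
    fig.colorbar(im, ax=ax, label="row z-score of log2 CPM")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
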