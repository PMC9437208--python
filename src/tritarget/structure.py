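"""Unsupervised cohort structure: sample PCA and UPGMA clustering.

PCA of normalized expression places samples on the first two principal
components (case/control separation, severity gradients); UPGMA
(average-linkage) hierarchical clustering orders genes and samples for
heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .de import NormalizedMatrix

__all__ = ["SampleEmbedding", "Dendrogram", "pca_samples", "upgma_linkage", "top_loading_genes"]


@dataclass
class SampleEmbedding:
    """Per-sample coordinates on the leading principal components."""

    coords: pd.DataFrame          # samples x PC1..PCk
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame        # genes x PC1..PCk

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must lie in [0,1] and sum <= 1")


@dataclass
class Dendrogram:
    """UPGMA merge list (scipy linkage encoding) plus display leaf order."""

    linkage: np.ndarray           # (n-1, 4): idx1, idx2, height, size
    labels: list[str]
    leaf_order: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("UPGMA merge heights must be non-decreasing")


def pca_samples(nm: NormalizedMatrix | pd.DataFrame, n_components: int = 2) -> SampleEmbedding:
    """PCA of samples on gene-wise mean-centered expression (SVD-based).

    Sign convention: each component's largest-magnitude gene loading is
    positive, making coordinates reproducible across runs.
    """
    logcpm = nm.logcpm if isinstance(nm, NormalizedMatrix) else nm
    if logcpm.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = logcpm.to_numpy(dtype=float).T            # samples x genes
    x = x - x.mean(axis=0, keepdims=True)         # gene-wise centering
    total_var = float((x ** 2).sum())
    if total_var <= 1e-12:
        raise ValueError("constant expression matrix: explained variance undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    comps = vt[:k]
    for i in range(k):  # sign convention
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    evr = (s ** 2) / (s ** 2).sum()
    cols = [f"PC{i + 1}" for i in range(k)]
    return SampleEmbedding(
        coords=pd.DataFrame(scores, index=logcpm.columns, columns=cols),
        explained_variance_ratio=evr[:k],
        loadings=pd.DataFrame(comps.T, index=logcpm.index, columns=cols),
    )


def top_loading_genes(emb: SampleEmbedding, n: int = 100, component: str = "PC1") -> list[str]:
    """Genes with the largest absolute loading on one component (heatmap pick)."""
    load = emb.loadings[component].abs().sort_values(ascending=False, kind="mergesort")
    return load.index[:n].tolist()


def upgma_linkage(
    matrix: pd.DataFrame, axis: str = "columns", metric: str = "euclidean"
) -> Dendrogram:
    """UPGMA (average-linkage) dendrogram over rows or columns.

    ``metric`` is "euclidean" or "correlation" (1 - Pearson r). Rows are
    typically genes and columns samples.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    if metric not in ("euclidean", "correlation"):
        raise ValueError("metric must be 'euclidean' or 'correlation'")
    data = matrix.to_numpy(dtype=float)
    labels = list(matrix.index if axis == "rows" else matrix.columns)
    if axis == "columns":
        data = data.T
    if len(labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = pdist(data, metric=metric)
    if not np.isfinite(dist).all():
        raise ValueError("non-finite distances (constant rows under correlation?)")
    z = hierarchy.linkage(dist, method="average")
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    return Dendrogram(linkage=z, labels=labels, leaf_order=order)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring for heatmap display; constant rows map to 0."""
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=0).replace(0.0, 1.0)
    return matrix.sub(mu, axis=0).div(sd, axis=0)
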