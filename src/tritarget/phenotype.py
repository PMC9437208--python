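"""Per-gene correlation between expression and a continuous phenotype.

Pearson correlation of normalized expression against a per-sample score
(e.g. normalized ankle dorsiflexion strength), with t-transform p-values,
BH adjustment within the tested gene subset, and ranked output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import NormalizedMatrix, bh_adjust

__all__ = ["gene_phenotype_correlation"]


def gene_phenotype_correlation(
    nm: NormalizedMatrix | pd.DataFrame,
    phenotype: pd.Series | None = None,
    gene_subset: set[str] | list[str] | None = None,
    include_controls: bool = True,
    condition: pd.Series | None = None,
) -> pd.DataFrame:
    """Pearson r of each gene's expression vs the phenotype score.

    Samples with missing phenotype are dropped pairwise; p from
    t = r*sqrt((n-2)/(1-r^2)) with n-2 df; q by BH within the tested
    subset. Zero-variance genes get NaN r and are excluded from BH
    (flagged in the ``degenerate`` column). Rows sorted by |r| descending.
    """
    if isinstance(nm, NormalizedMatrix):
        expr = nm.logcpm
        phenotype = nm.phenotype if phenotype is None else phenotype
        condition = nm.condition if condition is None else condition
    else:
        expr = nm
    if phenotype is None:
        raise ValueError("phenotype scores required")
    phenotype = phenotype.reindex(expr.columns)
    keep = phenotype.notna()
    if not include_controls:
        if condition is None:
            raise ValueError("condition labels needed to exclude controls")
        keep &= condition.reindex(expr.columns) == "case"
    cols = expr.columns[keep]
    n = len(cols)
    if n < 3:
        raise ValueError(f"need >=3 samples with phenotype, got {n}")
    y = phenotype[cols].to_numpy(float)
    if np.std(y) == 0:
        raise ValueError("phenotype is constant; correlation undefined")
    if gene_subset is not None:
        expr = expr.loc[expr.index.intersection(pd.Index(list(gene_subset)))]
    x = expr[cols].to_numpy(float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    degenerate = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    r[degenerate] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[degenerate] = np.nan
    q = np.full_like(p, np.nan)
    ok = ~degenerate
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    out = pd.DataFrame(
        {"r": r, "p": p, "q": q, "n": n, "degenerate": degenerate}, index=expr.index
    )
    out.index.name = "gene_id"
    return out.sort_values("r", key=lambda s: s.abs(), ascending=False, kind="mergesort")
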