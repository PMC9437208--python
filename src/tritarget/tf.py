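"""Repeat-bearing transcription factors: flagging, rank tests, network coverage.

Upstream TF-target enrichment engines (ChEA3-style) rank TFs by how
strongly their targets are over-represented in the DE genes. This module
consumes such a ranked table, flags TFs whose own transcript carries a
six-unit CTG/CAG run (a putative siRNA target), tests with a two-sample
Kolmogorov-Smirnov statistic whether repeat-bearing TFs occupy better
ranks than the remaining significant TFs, and measures how much of the DE
gene set a TF->gene network covers through repeat-bearing TFs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb, exp

import numpy as np
import pandas as pd

from .repeat_scan import MotifSpec, RepeatCatalog

logger = logging.getLogger(__name__)

__all__ = ["flag_repeat_tfs", "ks_rank_test", "KSResult", "RegulatoryNetwork", "network_coverage"]

DEFAULT_TF_SPEC = MotifSpec("CTG", min_units=6, max_mismatches=2)

# exact lattice-path DP is O(m*n); beyond this fall back to the asymptotic tail
_EXACT_LIMIT = 1_000_000


def flag_repeat_tfs(
    tf_table: pd.DataFrame, catalog: RepeatCatalog, spec: MotifSpec = DEFAULT_TF_SPEC
) -> pd.DataFrame:
    """Add a ``repeat_bearing`` column from catalog membership at ``spec``.

    TFs absent from the catalog background get NA (unknown) and are later
    excluded from the KS test with a logged count. ``tf_table`` needs
    ``tf_id`` and ``rank`` columns; a ``significant`` boolean column marks
    the upstream-FDR universe (default: all significant).
    """
    if spec not in catalog.sets:
        raise ValueError(f"catalog lacks spec {spec.label()}")
    out = tf_table.copy()
    if out["rank"].duplicated().any():
        raise ValueError("TF ranks must be unique")
    members = catalog.genes(spec)
    in_bg = out["tf_id"].isin(catalog.background)
    flags = out["tf_id"].isin(members).astype("boolean")
    flags[~in_bg] = pd.NA
    out["repeat_bearing"] = flags
    n_unknown = int((~in_bg).sum())
    if n_unknown:
        logger.info("%d TFs absent from catalog background (flag unknown)", n_unknown)
    if "significant" not in out.columns:
        out["significant"] = True
    return out


def _ks_statistic(rep: np.ndarray, other: np.ndarray, alternative: str) -> tuple[int, int, int]:
    """KS distance as an integer numerator over m*n (no ties: ranks unique).

    Returns (d_num, m, n) with D = d_num / (m*n). For 'less' (repeat ranks
    smaller, i.e. repeat ECDF above) D+ = max(F_rep - F_other).
    """
    m, n = rep.size, other.size
    pooled = np.concatenate([rep, other])
    is_rep = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
    order = np.argsort(pooled, kind="mergesort")
    steps = np.where(is_rep[order], n, -m)  # +n per repeat obs, -m per other
    path = np.cumsum(steps)                 # i*n - j*m after each observation
    if alternative == "less":
        d_num = int(path.max())
    elif alternative == "two-sided":
        d_num = int(np.abs(path).max())
    else:
        raise ValueError(f"unsupported alternative {alternative!r}")
    return max(d_num, 0), m, n


def _ks_exact_p(d_num: int, m: int, n: int, two_sided: bool) -> float:
    """Exact P(D >= d) by counting monotone lattice paths avoiding the band.

    Under the null all C(m+n, m) interleavings of the two samples are
    equally likely (ranks are distinct). A path visits states (i, j); the
    statistic exceeds the threshold iff i*n - j*m >= d_num (or |.| >= d_num
    two-sided) at some state. Integer arithmetic throughout.
    """
    if d_num <= 0:
        return 1.0
    counts = np.zeros((m + 1, n + 1), dtype=object)
    counts[0, 0] = 1
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            dev = i * n - j * m
            hit = (abs(dev) >= d_num) if two_sided else (dev >= d_num)
            if hit:
                counts[i, j] = 0
                continue
            c = 0
            if i > 0:
                c += counts[i - 1, j]
            if j > 0:
                c += counts[i, j - 1]
            counts[i, j] = c
    avoid = counts[m, n]
    total = comb(m + n, m)
    return float((total - avoid) / total)


@dataclass(frozen=True)
class KSResult:
    d: float
    p: float
    direction: str
    n_repeat: int
    n_other: int
    method: str


def ks_rank_test(tf_table: pd.DataFrame, alternative: str = "less") -> KSResult:
    """Two-sample KS on ranks of repeat-bearing vs remaining significant TFs.

    Default alternative 'less': repeat-bearing TFs occupy smaller (better)
    ranks. Exact p by lattice-path counting for moderate sizes, asymptotic
    exp(-2 D^2 mn/(m+n)) (one-sided) or Kolmogorov tail (two-sided) beyond.
    """
    table = tf_table[tf_table.get("significant", pd.Series(True, index=tf_table.index))]
    known = table[table["repeat_bearing"].notna()]
    n_excluded = len(table) - len(known)
    if n_excluded:
        logger.info("excluding %d TFs with unknown repeat status from KS test", n_excluded)
    rep = known.loc[known["repeat_bearing"].astype(bool), "rank"].to_numpy(float)
    other = known.loc[~known["repeat_bearing"].astype(bool), "rank"].to_numpy(float)
    m, n = rep.size, other.size
    if m < 3 or n < 3:
        raise ValueError(f"need >=3 TFs per group for the KS test, got {m} repeat vs {n} other")
    two_sided = alternative == "two-sided"
    d_num, m, n = _ks_statistic(rep, other, alternative)
    d = d_num / (m * n)
    if m * n <= _EXACT_LIMIT:
        p = _ks_exact_p(d_num, m, n, two_sided)
        method = "exact"
    else:
        en = m * n / (m + n)
        if two_sided:
            from scipy.special import kolmogorov

            p = float(kolmogorov(np.sqrt(en) * d))
        else:
            p = float(exp(-2.0 * en * d * d))
        method = "asymptotic"
    return KSResult(d=d, p=min(p, 1.0), direction=alternative, n_repeat=m, n_other=n, method=method)


@dataclass
class RegulatoryNetwork:
    """Directed TF -> gene edges with repeat/DE node attributes."""

    edges: pd.DataFrame            # columns tf_id, gene_id
    repeat_tfs: frozenset[str]
    de_status: pd.Series | None = None  # per-gene up/down/ns

    def __post_init__(self) -> None:
        if self.edges.duplicated(["tf_id", "gene_id"]).any():
            raise ValueError("duplicate TF->gene edges")

    @property
    def tfs(self) -> frozenset[str]:
        return frozenset(self.edges["tf_id"])

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.edges["gene_id"])


def network_coverage(
    net: RegulatoryNetwork,
    de_genes: set[str] | frozenset[str],
    up_genes: set[str] | frozenset[str] | None = None,
    down_genes: set[str] | frozenset[str] | None = None,
) -> dict:
    """Fraction of DE genes with >= 1 incoming edge from a repeat-bearing TF.

    Also reports per-TF out-degree into the DE set and the covered-gene
    bipartite edge list for plotting/export.
    """
    if not len(net.edges):
        raise ValueError("empty regulatory network")
    de = frozenset(de_genes)
    rep_edges = net.edges[net.edges["tf_id"].isin(net.repeat_tfs)]
    covered = frozenset(rep_edges["gene_id"]) & de

    def frac(subset: frozenset[str] | None) -> float | None:
        if subset is None:
            return None
        subset = frozenset(subset) & de
        return len(covered & subset) / len(subset) if subset else float("nan")

    de_edges = net.edges[net.edges["gene_id"].isin(de)]
    out_degree = (
        de_edges.groupby("tf_id").size().rename("n_de_targets").reset_index()
        .sort_values(["n_de_targets", "tf_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out_degree["repeat_bearing"] = out_degree["tf_id"].isin(net.repeat_tfs)
    return {
        "coverage_total": len(covered) / len(de) if de else float("nan"),
        "coverage_up": frac(up_genes),
        "coverage_down": frac(down_genes),
        "n_de": len(de),
        "n_covered": len(covered),
        "covered_genes": covered,
        "tf_out_degree": out_degree,
        "bipartite_edges": de_edges.reset_index(drop=True),
    }
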