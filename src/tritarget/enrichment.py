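"""Repeat-gene enrichment among DE genes, and generic over-representation.

The core statistic: among differentially expressed genes, is the number
carrying an endogenous repeat larger than expected from the prevalence of
repeat-bearing genes in the tissue-expressed background? Reported as an
observed/expected ratio with a Fisher exact p, over a grid of motifs,
repeat lengths, directions and fold-change thresholds. Control motifs
(CGG, CGT, GAA, GCG) form a separate multiple-testing family from the
CTG/CAG cells.

Fisher p-values are computed by exact integer hypergeometric
point-probability summation (numerators over a common denominator), so
tied terms are resolved exactly rather than by a floating-point slack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .de import bh_adjust, de_sets
from .repeat_scan import MotifSpec, RepeatCatalog, rotation_family

logger = logging.getLogger(__name__)

CONTROL_UNITS = ("CGG", "CGT", "GAA", "GCG")
_CTG_FAMILY = rotation_family("CTG")

__all__ = [
    "EnrichmentCell",
    "fisher_test_counts",
    "enrichment_cell",
    "enrichment_grid",
    "ora_gene_sets",
]


def _hypergeom_numerators(N: int, K: int, n: int) -> tuple[range, list[int]]:
    """Integer numerators of P(X=k) over the support, common denominator C(N,n)."""
    kmin, kmax = max(0, K + n - N), min(K, n)
    support = range(kmin, kmax + 1)
    return support, [comb(K, k) * comb(N - K, n - k) for k in support]


def fisher_test_counts(k: int, K: int, n: int, N: int, alternative: str = "two-sided") -> float:
    """Fisher exact p for overlap ``k`` of a size-``n`` draw against ``K``
    marked items in a universe of ``N``.

    two-sided: sum of all point probabilities <= P(X=k) (exact integer
    comparison); greater/less: hypergeometric tail sums.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid margins K={K}, n={n}, N={N}")
    support, nums = _hypergeom_numerators(N, K, n)
    if k not in support:
        raise ValueError(f"overlap {k} outside hypergeometric support {support}")
    total = comb(N, n)
    i = k - support.start
    if alternative == "greater":
        return min(1.0, sum(nums[i:]) / total)
    if alternative == "less":
        return min(1.0, sum(nums[: i + 1]) / total)
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    obs = nums[i]
    return min(1.0, sum(v for v in nums if v <= obs) / total)


@dataclass(frozen=True)
class EnrichmentCell:
    """One observed/expected cell of the motif x length x threshold grid."""

    spec: MotifSpec | None
    direction: str
    fc_threshold: float
    n_de_repeat: int
    n_de: int
    n_repeat_bg: int
    n_bg: int
    fisher_p: float
    q: float | None = None

    @property
    def expected(self) -> float:
        return self.n_de * self.n_repeat_bg / self.n_bg if self.n_bg else float("nan")

    @property
    def ratio(self) -> float:
        exp = self.expected
        if exp == 0:
            return float("nan") if self.n_de_repeat else 0.0
        return self.n_de_repeat / exp

    @property
    def displayable(self) -> bool:
        # display rule only: bars need >= 2 DE repeat genes; stats unaffected
        return self.n_de_repeat >= 2


def enrichment_cell(
    de_genes: Iterable[str],
    repeat_genes: Iterable[str],
    background: Iterable[str],
    spec: MotifSpec | None = None,
    direction: str = "both",
    fc_threshold: float = 1.0,
    alternative: str = "two-sided",
) -> EnrichmentCell:
    """Fisher 2x2 cell (DE/not x repeat-bearing/not) on the background."""
    bg = frozenset(background)
    if not bg:
        raise ValueError("empty background")
    de = frozenset(de_genes)
    rep = frozenset(repeat_genes)
    out_de, out_rep = len(de - bg), len(rep - bg)
    if out_de or out_rep:
        logger.info("dropped genes outside background: %d DE, %d repeat", out_de, out_rep)
    de &= bg
    rep &= bg
    k, K, n, N = len(de & rep), len(rep), len(de), len(bg)
    p = fisher_test_counts(k, K, n, N, alternative=alternative)
    return EnrichmentCell(
        spec=spec, direction=direction, fc_threshold=fc_threshold,
        n_de_repeat=k, n_de=n, n_repeat_bg=K, n_bg=N, fisher_p=p,
    )


def _family(spec: MotifSpec) -> str:
    return "ctg_cag" if spec.family == _CTG_FAMILY else "control"


def enrichment_grid(
    det: pd.DataFrame,
    catalog: RepeatCatalog,
    fc_thresholds: Sequence[float] = (1.0, 1.5, 2.0),
    directions: Sequence[str] = ("up", "down", "both"),
    alpha: float = 0.05,
    alternative: str = "two-sided",
    background: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One cell per (motif spec x fold-change threshold x direction).

    ``det`` must carry logFC and q columns; DE sets are re-derived at each
    threshold. The background defaults to the expression-filtered universe
    (the DE table's genes) intersected with the catalog background. BH
    adjustment runs separately within the CTG/CAG family and the
    control-motif family.
    """
    from .de import classify_de

    if background is None:
        background = set(det.index) & set(catalog.background)
    bg = frozenset(background)
    cells: list[EnrichmentCell] = []
    for fc in fc_thresholds:
        sets = de_sets(classify_de(det, fc_threshold=fc, alpha=alpha))
        for spec in catalog.specs:
            rep = catalog.genes(spec)
            for direction in directions:
                cells.append(
                    enrichment_cell(
                        sets[direction], rep, bg, spec=spec, direction=direction,
                        fc_threshold=fc, alternative=alternative,
                    )
                )
    rows = pd.DataFrame(
        {
            "unit": [c.spec.unit for c in cells],
            "k": [c.spec.min_units for c in cells],
            "m": [c.spec.max_mismatches for c in cells],
            "family": [_family(c.spec) for c in cells],
            "direction": [c.direction for c in cells],
            "fc_threshold": [c.fc_threshold for c in cells],
            "n_de_repeat": [c.n_de_repeat for c in cells],
            "n_de": [c.n_de for c in cells],
            "n_repeat_bg": [c.n_repeat_bg for c in cells],
            "n_bg": [c.n_bg for c in cells],
            "expected": [c.expected for c in cells],
            "ratio": [c.ratio for c in cells],
            "fisher_p": [c.fisher_p for c in cells],
            "displayable": [c.displayable for c in cells],
        }
    )
    rows["q"] = np.nan
    for fam in rows["family"].unique():
        mask = rows["family"] == fam
        rows.loc[mask, "q"] = bh_adjust(rows.loc[mask, "fisher_p"].to_numpy())
    return rows


def ora_gene_sets(
    genes: Iterable[str],
    background: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    min_size: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    Sets are intersected with the background; sets smaller than ``min_size``
    after intersection are skipped. One-sided upper-tail p per set, BH
    across the collection.
    """
    bg = frozenset(background)
    query = frozenset(genes) & bg
    if not collection:
        logger.warning("empty gene-set collection")
        return pd.DataFrame(
            columns=["set_name", "set_size", "overlap", "expected", "ratio", "p", "q"]
        )
    rows = []
    N, n = len(bg), len(query)
    for name, members in collection.items():
        mem = frozenset(members) & bg
        K = len(mem)
        if K < min_size:
            continue
        k = len(mem & query)
        p = fisher_test_counts(k, K, n, N, alternative="greater")
        expected = n * K / N
        rows.append(
            {
                "set_name": name, "set_size": K, "overlap": k, "expected": expected,
                "ratio": k / expected if expected else float("nan"), "p": p,
            }
        )
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "expected", "ratio", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def significant_set_count(ora: pd.DataFrame, alpha: float = 0.05) -> int:
    """Number of sets significant after BH (the histogram quantity)."""
    return int((ora["q"] < alpha).sum()) if len(ora) else 0
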