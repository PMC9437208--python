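"""Cross-cohort comparison of DE genes and repeat-gene replication.

Venn-style counts of genes differentially expressed in exactly 1..n
cohorts (all DE genes and the repeat-bearing subset), and a Fisher test of
whether repeat-bearing DE genes in a reference tissue replicate in at
least one other cohort more often than the remaining DE genes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .enrichment import fisher_test_counts

__all__ = ["CohortDESummary", "venn_counts", "repeat_overlap_test", "OverlapTestResult"]


@dataclass(frozen=True)
class CohortDESummary:
    """One cohort's DE gene sets at a stated threshold, with repeat subset."""

    name: str
    up: frozenset[str]
    down: frozenset[str]
    repeat_genes: frozenset[str] = frozenset()
    fc_threshold: float = 1.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        stray = self.repeat_genes - self.de
        if stray:
            raise ValueError(
                f"{self.name}: repeat subset contains non-DE genes, e.g. {sorted(stray)[:3]}"
            )

    @property
    def de(self) -> frozenset[str]:
        return self.up | self.down


def venn_counts(cohorts: list[CohortDESummary]) -> pd.DataFrame:
    """Genes DE in exactly 1, 2, ..., n cohorts; all DE genes and the
    repeat-bearing subset (union of per-cohort repeat subsets)."""
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    mult = Counter()
    for c in cohorts:
        for g in c.de:
            mult[g] += 1
    repeat_union = frozenset().union(*(c.repeat_genes for c in cohorts))
    rows = []
    for n in range(1, len(cohorts) + 1):
        genes_n = [g for g, m in mult.items() if m == n]
        rows.append(
            {
                "n_cohorts": n,
                "n_genes": len(genes_n),
                "n_repeat_genes": sum(g in repeat_union for g in genes_n),
            }
        )
    out = pd.DataFrame(rows)
    assert out["n_genes"].sum() == len(mult)
    return out


@dataclass(frozen=True)
class OverlapTestResult:
    frac_repeat: float
    frac_other: float
    p: float
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: repeat, other; cols: replicate, not


def repeat_overlap_test(
    reference: CohortDESummary,
    others: list[CohortDESummary],
    direction_matched: bool = False,
    alternative: str = "greater",
) -> OverlapTestResult:
    """Do repeat-bearing DE genes of the reference cohort replicate (appear
    DE in >=1 other cohort) more often than the remaining DE genes?

    Default overlap is direction-agnostic (a gene counts as replicating if
    DE in any direction elsewhere); ``direction_matched`` requires the same
    direction. One-sided Fisher toward greater repeat-gene replication.
    """
    if not others:
        raise ValueError("need at least one comparison cohort")
    rep = reference.repeat_genes
    other_genes = reference.de - rep
    if not rep or not other_genes:
        raise ValueError("reference DE partition has an empty row (no repeat or no remaining genes)")

    def replicates(g: str) -> bool:
        for c in others:
            if direction_matched:
                if (g in reference.up and g in c.up) or (g in reference.down and g in c.down):
                    return True
            elif g in c.de:
                return True
        return False

    a = sum(replicates(g) for g in rep)
    b = len(rep) - a
    c_ = sum(replicates(g) for g in other_genes)
    d = len(other_genes) - c_
    N, K, n, k = a + b + c_ + d, a + b, a + c_, a
    p = fisher_test_counts(k, K, n, N, alternative=alternative)
    return OverlapTestResult(
        frac_repeat=a / (a + b),
        frac_other=c_ / (c_ + d),
        p=p,
        table=((a, b), (c_, d)),
    )
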