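"""Independent reference implementations used only by the test suite.

These deliberately avoid the library's algorithms: the repeat oracle
enumerates every window x rotation explicitly, the Fisher oracle sums
exact integer hypergeometric numerators in a literal loop, BH is a
literal step-up, UPGMA is a naive cluster-list agglomerator, and the KS
oracle enumerates rank assignments exhaustively.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def brute_scan(seq: str, spec) -> list[tuple[int, int, str, int]]:
    """Exhaustive repeat scan: every start x every rotation x both units.

    Returns (start, n_units, matched_unit, n_mismatches) tuples sorted by
    (start, unit), using the same merge rule as the scanner but computed
    from first principles.
    """
    from tritarget.repeat_scan import reverse_complement

    window = 3 * spec.min_units
    n = len(seq)
    enc = np.frombuffer(seq.encode(), dtype=np.uint8)
    results = []
    units = [spec.unit]
    if spec.include_complement:
        rc = reverse_complement(spec.unit)
        if rc != spec.unit:
            units.append(rc)
    units = sorted(set(units))
    if n < window:
        return []
    windows = sliding_window_view(enc, window)
    claimed: set[tuple[int, int]] = set()
    for unit in units:
        patterns = []
        for r in range(3):
            rot = unit[r:] + unit[:r]
            patterns.append(np.frombuffer((rot * spec.min_units).encode(), dtype=np.uint8))
        mism = np.stack([(windows != pat).sum(axis=1) for pat in patterns]).min(axis=0)
        qual = [i for i in range(len(mism)) if mism[i] <= spec.max_mismatches]
        # merge overlapping qualifying windows
        i = 0
        while i < len(qual):
            j = i
            while j + 1 < len(qual) and qual[j + 1] < qual[j] + window:
                j += 1
            start, end = qual[i], qual[j] + window
            n_units = (end - start) // 3
            mmin = min(int(mism[q]) for q in qual[i : j + 1])
            if (start, n_units) not in claimed:
                claimed.add((start, n_units))
                results.append((start, n_units, unit, mmin))
            i = j + 1
    results.sort(key=lambda t: (t[0], t[2]))
    return results


def bh_stepup(p: list[float]) -> list[float]:
    """Literal BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        rank = pos + 1
        candidates = []
        for pos2 in range(pos, m):
            j = order[pos2]
            candidates.append(p[j] * m / (pos2 + 1))
        q[i] = min(1.0, min(candidates))
    return q


def fisher_two_sided_exact(k: int, K: int, n: int, N: int) -> float:
    """Two-sided Fisher by literal point-probability summation over the
    support, with exact integer numerators over the common denominator."""
    kmin, kmax = max(0, K + n - N), min(K, n)
    nums = [comb(K, j) * comb(N - K, n - j) for j in range(kmin, kmax + 1)]
    obs = nums[k - kmin]
    total = 0
    for v in nums:
        if v <= obs:
            total += v
    return total / comb(N, n)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    kmin, kmax = max(0, K + n - N), min(K, n)
    total = 0
    for j in range(max(k, kmin), kmax + 1):
        total += comb(K, j) * comb(N - K, n - j)
    return total / comb(N, n)


def upgma_cophenetic(dist: np.ndarray) -> np.ndarray:
    """Naive UPGMA on a square distance matrix -> cophenetic matrix.

    Cluster distances are recomputed each step as the arithmetic mean of
    all original pairwise distances between members.
    """
    n = dist.shape[0]
    clusters = [[i] for i in range(n)]
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def ks_plus_pvalues(m: int, n: int) -> dict[int, float]:
    """Exact null distribution of the one-sided KS statistic D+ for two
    samples of distinct ranks, by exhaustive enumeration of assignments.

    Returns {d_num: P(D+ >= d_num / (m*n))}.
    """
    total = comb(m + n, m)
    d_counts: dict[int, int] = {}
    for rep_idx in itertools.combinations(range(m + n), m):
        rep = set(rep_idx)
        i = j = 0
        d_num = 0
        for pos in range(m + n):  # ranks in increasing order
            if pos in rep:
                i += 1
            else:
                j += 1
            d_num = max(d_num, i * n - j * m)
        d_counts[d_num] = d_counts.get(d_num, 0) + 1
    pvals = {}
    for d in sorted(d_counts):
        pvals[d] = sum(c for dd, c in d_counts.items() if dd >= d) / total
    return pvals
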