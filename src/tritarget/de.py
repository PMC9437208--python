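"""Gene-level differential expression for case/control count matrices.

The paper-style workflow: filter genes below 1 CPM, TMM between-sample
normalization, log2-CPM with a 0.5 prior count, a variance-moderated
two-sample t test (a documented surrogate for limma-voom's moderated
statistics), Benjamini-Hochberg FDR, and up/down classification at a
fold-change threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "EmptyResultError",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "de_test",
    "bh_adjust",
    "classify_de",
    "run_de",
]


class EmptyResultError(RuntimeError):
    """All genes removed by a filter: downstream analysis has no input."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts with per-sample condition labels.

    ``counts`` is genes (rows) x samples (columns); ``condition`` maps each
    sample to "case" or "control"; ``phenotype`` is an optional per-sample
    continuous score (e.g. normalized dorsiflexion strength).
    """

    counts: pd.DataFrame
    condition: pd.Series
    phenotype: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.is_unique:
            dups = self.counts.index[self.counts.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.condition = self.condition.reindex(self.counts.columns)
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise ValueError(f"samples without condition label: {missing[:5]}")
        bad = set(self.condition.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"condition labels must be case/control, got {sorted(bad)}")
        if self.phenotype is not None:
            self.phenotype = self.phenotype.reindex(self.counts.columns)

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        return self.counts / self.lib_size * 1e6


@dataclass
class NormalizedMatrix:
    """log2-CPM expression with TMM factors and library sizes."""

    logcpm: pd.DataFrame
    tmm_factor: pd.Series
    lib_size: pd.Series
    condition: pd.Series | None = None
    phenotype: pd.Series | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.logcpm.to_numpy()).all():
            raise ValueError("logcpm must be finite")
        if (self.tmm_factor <= 0).any():
            raise ValueError("TMM factors must be positive")


def filter_low_expression(cm: CountMatrix, min_cpm: float = 1.0) -> CountMatrix:
    """Keep genes with CPM > ``min_cpm`` in *every* sample of at least one
    condition (genes expressed in neither condition are dropped)."""
    lib = cm.lib_size
    if (lib <= 0).any():
        empty = lib.index[lib <= 0].tolist()
        raise ValueError(f"samples with zero library size: {empty[:5]}")
    cpm = cm.cpm()
    keep = pd.Series(False, index=cm.genes)
    for cond in (CASE, CONTROL):
        cols = cm.samples[cm.condition == cond]
        if len(cols):
            keep |= (cpm[cols] > min_cpm).all(axis=1)
    if not keep.any():
        raise EmptyResultError("no genes pass the expression filter")
    n_drop = int((~keep).sum())
    logger.info("expression filter: kept %d genes, removed %d", int(keep.sum()), n_drop)
    return CountMatrix(cm.counts.loc[keep], cm.condition.copy(), cm.phenotype)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """Trimmed, weighted mean of M-values of one sample against the reference.

    M and A are computed on library-normalized abundances; genes with a zero
    in either sample are excluded; the trims remove the extreme 30% of M
    (each tail) and 5% of A; weights are inverse asymptotic (delta-method)
    variances of M under Poisson counts.
    """
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return np.nan
    o, r = obs[ok].astype(float), ref[ok].astype(float)
    p_o, p_r = o / lib_obs, r / lib_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    if np.allclose(m, m[0]):
        # all M identical (e.g. pure depth difference): trimming is vacuous
        return float(m[0])
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return float(np.average(m, weights=w))
    return float(np.average(m[keep], weights=w[keep]))


def tmm_factors(cm: CountMatrix) -> pd.Series:
    """TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the column whose 75th-percentile CPM is closest
    to the mean of those percentiles across samples.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    counts = cm.counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("TMM needs positive library sizes")
    q75 = np.percentile(counts / lib * 1e6, 75, axis=0)
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = counts[:, ref_idx]
    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        f = _tmm_pair(counts[:, j], ref, lib[j], lib[ref_idx])
        if np.isnan(f):
            logger.warning(
                "sample %s shares no expressed gene with the reference; factor set to 1",
                cm.samples[j],
            )
            f = 0.0
        log_factors[j] = f
    log_factors -= log_factors.mean()  # geometric mean 1
    return pd.Series(2.0 ** log_factors, index=cm.samples, name="tmm_factor")


def log_cpm(cm: CountMatrix, factors: pd.Series | None = None, prior_count: float = 0.5) -> NormalizedMatrix:
    """log2((count + prior) / (lib_size * factor + 1) * 1e6) per gene/sample."""
    if factors is None:
        factors = pd.Series(1.0, index=cm.samples)
    factors = factors.reindex(cm.samples)
    if (factors <= 0).any() or factors.isna().any():
        raise ValueError("normalization factors must be positive for every sample")
    eff = cm.lib_size * factors + 1.0
    logcpm = np.log2((cm.counts + prior_count) / eff * 1e6)
    return NormalizedMatrix(
        logcpm=logcpm,
        tmm_factor=factors,
        lib_size=cm.lib_size,
        condition=cm.condition,
        phenotype=cm.phenotype,
    )


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order kept)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_test(nm: NormalizedMatrix, condition: pd.Series | None = None, d0: float = 4.0) -> pd.DataFrame:
    """Moderated two-sample t test per gene on log2-CPM.

    The pooled per-gene variance s2_g (d_g = n1+n2-2 df) is shrunk toward
    s0^2 (the median pooled variance) with prior df d0; the statistic is
    referred to a t distribution with d0 + d_g df. This is a surrogate for
    limma-voom's empirical-Bayes moderation (no precision weights).
    """
    if condition is None:
        condition = nm.condition
    if condition is None:
        raise ValueError("condition labels required")
    condition = condition.reindex(nm.logcpm.columns)
    case_cols = condition.index[condition == CASE]
    ctrl_cols = condition.index[condition == CONTROL]
    n1, n2 = len(case_cols), len(ctrl_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per condition, got case={n1} control={n2}")
    x1 = nm.logcpm[case_cols].to_numpy()
    x2 = nm.logcpm[ctrl_cols].to_numpy()
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    logfc = m1 - m2
    ss1 = ((x1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((x2 - m2[:, None]) ** 2).sum(axis=1)
    dg = n1 + n2 - 2
    s2 = (ss1 + ss2) / dg
    s0_sq = float(np.median(s2))
    if s0_sq <= 0:
        s0_sq = np.finfo(float).tiny  # fully degenerate input; keep test defined
    s2_mod = (d0 * s0_sq + dg * s2) / (d0 + dg)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = logfc / se
    p = 2.0 * stats.t.sf(np.abs(t), df=d0 + dg)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    det = pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "q": bh_adjust(p)}, index=nm.logcpm.index
    )
    det.index.name = "gene_id"
    return det


def classify_de(det: pd.DataFrame, fc_threshold: float = 1.5, alpha: float = 0.05) -> pd.DataFrame:
    """Add an up/down/ns status column at a fold-change threshold.

    ``fc_threshold=1`` recovers significance-only classification.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold must be >= 1")
    lfc_cut = np.log2(fc_threshold)
    out = det.copy()
    sig = out["q"] < alpha
    status = np.where(
        sig & (out["logFC"] >= lfc_cut), "up",
        np.where(sig & (out["logFC"] <= -lfc_cut), "down", "ns"),
    )
    out["status"] = status
    return out


def de_sets(det: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Gene sets by status from a classified DE table."""
    return {
        "up": frozenset(det.index[det["status"] == "up"]),
        "down": frozenset(det.index[det["status"] == "down"]),
        "both": frozenset(det.index[det["status"] != "ns"]),
    }


def run_de(cm: CountMatrix, fc_threshold: float = 1.5, alpha: float = 0.05,
           d0: float = 4.0, min_cpm: float = 1.0, prior_count: float = 0.5
           ) -> tuple[CountMatrix, NormalizedMatrix, pd.DataFrame]:
    """Filter, normalize, test and classify in one call."""
    filtered = filter_low_expression(cm, min_cpm=min_cpm)
    factors = tmm_factors(filtered)
    nm = log_cpm(filtered, factors, prior_count=prior_count)
    det = classify_de(de_test(nm, d0=d0), fc_threshold=fc_threshold, alpha=alpha)
    return filtered, nm, det
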