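"""Differential expression: filter, TMM, log-CPM, moderated t, BH, classify."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _oracles import bh_stepup
from tritarget.de import (
    CountMatrix,
    EmptyResultError,
    NormalizedMatrix,
    bh_adjust,
    classify_de,
    de_test,
    filter_low_expression,
    log_cpm,
    tmm_factors,
)


def make_cm(counts, n_case, n_control, genes=None):
    n = counts.shape[0]
    genes = genes or [f"g{i}" for i in range(n)]
    samples = [f"s{i}" for i in range(counts.shape[1])]
    cond = ["control"] * n_control + ["case"] * n_case
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        condition=pd.Series(cond, index=samples),
    )


class TestFilter:
    def test_zero_gene_removed_and_one_condition_rule(self):
        counts = np.array([
            [0, 0, 0, 0],       # all zero -> removed
            [500, 500, 0, 0],   # expressed in controls only -> kept
            [0, 0, 500, 500],   # expressed in cases only -> kept
            [500, 0, 0, 0],     # high in one control sample only -> removed
            [900, 900, 900, 900],
        ])
        cm = make_cm(counts, n_case=2, n_control=2)
        kept = filter_low_expression(cm)
        assert list(kept.genes) == ["g1", "g2", "g4"]

    def test_matches_independent_cpm_recomputation(self, rng):
        counts = rng.negative_binomial(5, 0.01, size=(400, 8))
        counts[rng.random(400) < 0.1] = 0
        cm = make_cm(counts, n_case=4, n_control=4)
        kept = set(filter_low_expression(cm).genes)
        lib = counts.sum(axis=0)
        expected = set()
        for i in range(400):
            cpm = counts[i] / lib * 1e6
            if (cpm[:4] > 1).all() or (cpm[4:] > 1).all():
                expected.add(f"g{i}")
        assert kept == expected

    def test_all_removed_signals(self):
        cm = make_cm(np.array([[1, 0, 0, 1], [0, 1, 1, 0]]) * 0, 2, 2)
        cm.counts.iloc[0, 0] = 1  # keep library sizes positive
        cm.counts.iloc[1, 1] = 1
        cm.counts.iloc[0, 2] = 1
        cm.counts.iloc[1, 3] = 1
        with pytest.raises(EmptyResultError):
            filter_low_expression(cm, min_cpm=1e6)


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        counts = np.tile(np.arange(1, 101)[:, None], (1, 6))
        f = tmm_factors(make_cm(counts, 3, 3))
        assert np.allclose(f, 1.0)

    def test_scale_invariance(self, rng):
        """Depth is carried by the library size: scaling one sample's counts
        leaves every TMM factor (composition adjustment) unchanged."""
        counts = rng.negative_binomial(10, 0.02, size=(800, 6)) + 1
        cm = make_cm(counts, 3, 3)
        f0 = tmm_factors(cm)
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 4
        f1 = tmm_factors(make_cm(scaled.astype(int), 3, 3))
        assert np.allclose(f0, f1, rtol=0.02)

    def test_composition_bias_corrected(self):
        """A sample where 10% of genes are 8x inflated: TMM factors must
        equalize the normalized abundance of the unchanged genes."""
        counts = np.full((1000, 2), 100)
        counts[:100, 1] = 800
        cm = make_cm(counts, 1, 1)
        # condition labels irrelevant for factors; need >=1 per group though
        cm = CountMatrix(counts=cm.counts, condition=pd.Series(
            ["case", "control"], index=cm.samples))
        f = tmm_factors(cm)
        lib = cm.lib_size
        norm_cpm = counts[500] / (lib * f) * 1e6
        assert norm_cpm.iloc[0] == pytest.approx(norm_cpm.iloc[1], rel=0.01)
        assert np.prod(f) == pytest.approx(1.0)

    def test_sample_permutation_symmetry(self, rng):
        counts = rng.negative_binomial(10, 0.02, size=(500, 5)) + 1
        cm = make_cm(counts, 3, 2)
        f = tmm_factors(cm)
        perm = [3, 0, 4, 1, 2]
        cm2 = CountMatrix(counts=cm.counts.iloc[:, perm],
                          condition=cm.condition.iloc[perm])
        f2 = tmm_factors(cm2)
        assert np.allclose(f[cm2.samples], f2)


class TestLogCpm:
    def test_formula_at_zero_count(self):
        counts = np.zeros((1, 2), dtype=int)
        counts[0] = [0, 0]
        cm = make_cm(np.array([[0, 0], [999998, 999998]]), 1, 1)
        cm = CountMatrix(counts=cm.counts,
                         condition=pd.Series(["case", "control"], index=cm.samples))
        nm = log_cpm(cm, pd.Series(1.0, index=cm.samples))
        # count 0, lib ~1e6, factor 1 -> log2(0.5/(1e6+1)*1e6) ~ -1.0
        assert nm.logcpm.iloc[0, 0] == pytest.approx(-1.0, abs=1e-4)

    def test_scale_invariance_and_monotonicity(self, rng):
        # doubling counts and libraries is invariant up to the fixed 0.5
        # prior, whose effect is O(prior/count)
        counts = rng.integers(100, 2000, size=(100, 4))
        cm = make_cm(counts, 2, 2)
        nm = log_cpm(cm)
        cm2 = make_cm(counts * 2, 2, 2)
        nm2 = log_cpm(cm2)
        assert np.allclose(nm.logcpm, nm2.logcpm, atol=0.01)
        col = nm.logcpm.iloc[:, 0]
        order = np.argsort(counts[:, 0], kind="stable")
        assert (np.diff(col.iloc[order]) >= -1e-12).all()


class TestBH:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_all_ones(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_literal_stepup_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(30):
            p = rng.random(int(rng.integers(1, 40))).clip(1e-9, 1.0)
            q = bh_adjust(p)
            assert np.allclose(q, bh_stepup(list(p)), atol=1e-12)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def _nm_from_array(x, n_case, n_control):
    genes = [f"g{i}" for i in range(x.shape[0])]
    samples = [f"s{i}" for i in range(x.shape[1])]
    cond = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    return NormalizedMatrix(
        logcpm=pd.DataFrame(x, index=genes, columns=samples),
        tmm_factor=pd.Series(1.0, index=samples),
        lib_size=pd.Series(1e6, index=samples),
        condition=cond,
    )


class TestModeratedT:
    def test_label_swap_negates_logfc(self, rng):
        x = rng.normal(size=(200, 10))
        nm = _nm_from_array(x, 5, 5)
        det = de_test(nm)
        flipped = nm.condition.map({"case": "control", "control": "case"})
        det2 = de_test(nm, condition=flipped)
        assert np.array_equal(det["logFC"].to_numpy(), -det2["logFC"].to_numpy())

    def test_null_p_uniform(self, rng):
        x = rng.normal(size=(2000, 20))
        det = de_test(_nm_from_array(x, 10, 10))
        assert stats.kstest(det["p"], "uniform").pvalue > 0.01

    def test_planted_effect_power(self):
        """A 2-log2FC shift at sigma 0.5, 10v10, is detected at q<0.05
        in >=95% of planted genes across seeds."""
        detected = total = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(scale=0.5, size=(500, 20))
            x[:10, :10] += 2.0
            det = de_test(_nm_from_array(x, 10, 10))
            detected += (det["q"][:10] < 0.05).sum()
            total += 10
        assert detected / total >= 0.95

    def test_zero_variance_handled(self):
        x = np.zeros((5, 8))
        x[0, :4] = 1.0
        det = de_test(_nm_from_array(x, 4, 4))
        assert np.isfinite(det["p"]).all()

    def test_determinism(self, rng):
        x = rng.normal(size=(100, 8))
        nm = _nm_from_array(x, 4, 4)
        assert de_test(nm).equals(de_test(nm))


class TestClassify:
    @pytest.mark.parametrize(
        "logfc,q,fc,expected",
        [
            (0.4, 0.001, 1.5, "ns"),    # below log2(1.5) ~ 0.585
            (1.0, 0.2, 1.5, "ns"),      # fails alpha
            (0.1, 0.01, 1.0, "up"),     # threshold 1 = significance-only
            (-0.7, 0.01, 1.5, "down"),
            (0.59, 0.01, 1.5, "up"),
        ],
    )
    def test_threshold_arithmetic(self, logfc, q, fc, expected):
        det = pd.DataFrame({"logFC": [logfc], "t": [0.0], "p": [q], "q": [q]},
                           index=["g0"])
        assert classify_de(det, fc_threshold=fc)["status"].iloc[0] == expected

    def test_rejects_threshold_below_one(self):
        det = pd.DataFrame({"logFC": [0.0], "t": [0.0], "p": [1.0], "q": [1.0]})
        with pytest.raises(ValueError):
            classify_de(det, fc_threshold=0.5)
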