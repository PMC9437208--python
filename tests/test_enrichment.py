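"""Fisher/hypergeometric enrichment cells, grids and ORA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from _oracles import fisher_two_sided_exact, hypergeom_upper_tail
from tritarget.de import classify_de
from tritarget.enrichment import (
    enrichment_cell,
    enrichment_grid,
    fisher_test_counts,
    ora_gene_sets,
    significant_set_count,
)
from tritarget.repeat_scan import MotifSpec, RepeatCatalog
from tritarget.simulate import SimTruth, assign_repeat_labels, simulate_gene_sets


def _sets(n_bg, n_rep, n_de, overlap):
    bg = [f"g{i}" for i in range(n_bg)]
    rep = set(bg[:n_rep])
    de = set(bg[:overlap]) | set(bg[n_rep : n_rep + n_de - overlap])
    return de, rep, set(bg)


class TestCell:
    def test_exact_expectation_ratio_one(self):
        de, rep, bg = _sets(1000, 100, 50, 5)
        cell = enrichment_cell(de, rep, bg)
        assert cell.expected == pytest.approx(5.0)
        assert cell.ratio == pytest.approx(1.0)
        assert cell.displayable

    def test_enriched_cell_matches_oracle(self):
        de, rep, bg = _sets(1000, 100, 50, 20)
        cell = enrichment_cell(de, rep, bg)
        assert cell.ratio == pytest.approx(4.0)
        assert cell.fisher_p == pytest.approx(
            fisher_two_sided_exact(20, 100, 50, 1000), abs=1e-12
        )

    def test_zero_overlap_not_displayable(self):
        de, rep, bg = _sets(1000, 100, 50, 0)
        cell = enrichment_cell(de, rep, bg)
        assert cell.ratio == 0.0 and not cell.displayable

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="empty background"):
            enrichment_cell({"a"}, {"a"}, set())

    def test_outside_background_dropped(self):
        cell = enrichment_cell({"a", "zz"}, {"a", "yy"}, {"a", "b", "c", "d"})
        assert cell.n_de == 1 and cell.n_repeat_bg == 1


class TestFisher:
    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            N = int(rng.integers(10, 400))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            kmin, kmax = max(0, K + n - N), min(K, n)
            k = int(rng.integers(kmin, kmax + 1))
            table = [[k, K - k], [n - k, N - K - n + k]]
            assert fisher_test_counts(k, K, n, N) == pytest.approx(
                fisher_exact(table)[1], rel=1e-6, abs=1e-12
            )
            assert fisher_test_counts(k, K, n, N, "greater") == pytest.approx(
                hypergeom_upper_tail(k, K, n, N), abs=1e-12
            )

    def test_invalid_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_test_counts(0, 5, 3, 4)
        with pytest.raises(ValueError):
            fisher_test_counts(4, 3, 5, 10)


def _grid_inputs(rng, n_bg=400):
    genes = [f"g{i}" for i in range(n_bg)]
    det = pd.DataFrame(
        {
            "logFC": rng.normal(0, 1.2, n_bg),
            "t": 0.0,
            "p": rng.random(n_bg).clip(1e-6),
        },
        index=genes,
    )
    from tritarget.de import bh_adjust

    det["q"] = bh_adjust(det["p"].to_numpy())
    sets = {
        MotifSpec("CTG", 6, 0): frozenset(genes[:40]),
        MotifSpec("CGG", 6, 0): frozenset(genes[40:80]),
        MotifSpec("GAA", 6, 0): frozenset(genes[80:120]),
    }
    catalog = RepeatCatalog(sets=sets, background=frozenset(genes))
    return det, catalog


class TestGrid:
    def test_monotone_in_threshold_and_direction_partition(self, rng):
        det, catalog = _grid_inputs(rng)
        grid = enrichment_grid(det, catalog, fc_thresholds=[1.0, 1.5, 2.0])
        for (unit, direction), sub in grid.groupby(["unit", "direction"]):
            sub = sub.sort_values("fc_threshold")
            assert (sub["n_de"].diff().dropna() <= 0).all()
        for (unit, fc), sub in grid.groupby(["unit", "fc_threshold"]):
            by_dir = sub.set_index("direction")
            assert (
                by_dir.loc["both", "n_de_repeat"]
                == by_dir.loc["up", "n_de_repeat"] + by_dir.loc["down", "n_de_repeat"]
            )
            assert by_dir.loc["both", "n_de"] == by_dir.loc["up", "n_de"] + by_dir.loc["down", "n_de"]

    def test_family_split_bh(self, rng):
        det, catalog = _grid_inputs(rng)
        grid = enrichment_grid(det, catalog, fc_thresholds=[1.0])
        from tritarget.de import bh_adjust

        for fam, sub in grid.groupby("family"):
            assert np.allclose(sub["q"], bh_adjust(sub["fisher_p"].to_numpy()))
        assert set(grid["family"]) == {"ctg_cag", "control"}

    def test_row_count(self, rng):
        det, catalog = _grid_inputs(rng)
        grid = enrichment_grid(det, catalog, fc_thresholds=[1.0, 1.5, 2.0])
        assert len(grid) == 3 * 3 * 3  # specs x thresholds x directions


class TestORA:
    def test_query_itself_is_top_hit(self, rng):
        bg = [f"g{i}" for i in range(500)]
        query = set(bg[:50])
        collection = {"self": query, "random": set(bg[100:180])}
        ora = ora_gene_sets(query, bg, collection)
        assert ora.iloc[0]["set_name"] == "self"
        assert ora.iloc[0]["p"] < 1e-20

    def test_small_sets_skipped_and_empty_collection(self, rng):
        bg = [f"g{i}" for i in range(100)]
        ora = ora_gene_sets(set(bg[:10]), bg, {"tiny": {"g0", "g1"}})
        assert len(ora) == 0
        assert len(ora_gene_sets(set(bg[:10]), bg, {})) == 0

    def test_null_calibration(self):
        """Random sets vs a random query: ~5% of raw p below 0.05."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bg = [f"g{i}" for i in range(2000)]
            query = set(rng.choice(bg, 100, replace=False))
            collection = {
                f"s{i}": set(rng.choice(bg, 60, replace=False)) for i in range(80)
            }
            ora = ora_gene_sets(query, bg, collection)
            fracs.append((ora["p"] < 0.05).mean())
        assert 0.01 <= np.mean(fracs) <= 0.075  # hypergeom p is super-uniform

    def test_recovers_planted_enriched_sets(self):
        truth = SimTruth(seed=11)
        labels = assign_repeat_labels(truth)
        rng = np.random.default_rng(11)
        universe = list(labels.index)
        up = list(rng.choice(universe, 60, replace=False))
        collection, enriched = simulate_gene_sets(truth, up, universe)
        ora = ora_gene_sets(set(up), universe, collection)
        called = set(ora.loc[ora["q"] < 0.05, "set_name"])
        sensitivity = len(called & enriched) / len(enriched)
        assert sensitivity >= 0.8
        assert significant_set_count(ora) == len(called)
        # no planted signal among null sets leaking through
        fdr = len(called - enriched) / max(len(called), 1)
        assert fdr <= 0.2
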