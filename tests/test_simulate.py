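"""Synthetic cohort generator: determinism, planted truth, round trips."""

import numpy as np
import pandas as pd
import pytest

from tritarget.repeat_scan import MotifSpec, build_catalog, scan_sequence
from tritarget.simulate import (
    SimTruth,
    assign_repeat_labels,
    expected_catalog,
    preset_truth,
    simulate_counts,
    simulate_gene_sets,
    simulate_tf_table,
    simulate_transcripts,
    truth_to_json,
    write_cohort,
)


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        truth = SimTruth(seed=42, n_genes=200)
        a = simulate_counts(truth, n_case=4, n_control=3)
        b = simulate_counts(truth, n_case=4, n_control=3)
        assert a.counts.counts.equals(b.counts.counts)
        assert a.gene_truth.equals(b.gene_truth)
        assert a.counts.phenotype.equals(b.counts.phenotype)

    def test_distinct_seeds_differ(self):
        a = simulate_counts(SimTruth(seed=1, n_genes=200), n_case=3, n_control=3)
        b = simulate_counts(SimTruth(seed=2, n_genes=200), n_case=3, n_control=3)
        assert not a.counts.counts.equals(b.counts.counts)

    def test_transcripts_reproducible(self):
        truth = SimTruth(seed=5, n_genes=30, seq_length=400)
        ra, la = simulate_transcripts(truth)
        rb, lb = simulate_transcripts(truth)
        assert ra == rb and la.equals(lb)


class TestTranscripts:
    def test_scanner_recovers_exactly_the_planted_set(self):
        truth = SimTruth(seed=7, n_genes=120, seq_length=600,
                         repeat_prevalence={"CTG": 0.12, "CGG": 0.05})
        records, labels = simulate_transcripts(truth)
        specs = [MotifSpec(u, k, m) for u in ("CTG", "CGG")
                 for k, m in ((4, 0), (6, 0), (6, 2))]
        cat = build_catalog(records, specs)
        for spec in specs:
            assert cat.genes(spec) == expected_catalog(truth, labels, spec), spec.label()

    def test_zero_prevalence_yields_no_hits(self):
        truth = SimTruth(seed=3, n_genes=40, seq_length=500, repeat_prevalence={})
        records, _ = simulate_transcripts(truth)
        for _, seq in records:
            assert scan_sequence(seq, MotifSpec("CTG", 4, 0)) == []

    def test_longer_planted_runs_nest(self):
        truth = SimTruth(seed=7, n_genes=60, seq_length=500, planted_units=7,
                         repeat_prevalence={"CTG": 0.2})
        records, labels = simulate_transcripts(truth)
        cat = build_catalog(records, [MotifSpec("CTG", 6, 0), MotifSpec("CTG", 7, 0)])
        planted = expected_catalog(truth, labels, MotifSpec("CTG", 6, 0))
        assert cat.genes(MotifSpec("CTG", 7, 0)) == planted
        assert cat.genes(MotifSpec("CTG", 6, 0)) == planted  # 7-run contains a 6-run

    def test_infeasible_configuration_signals(self):
        # sequence shorter than the planted run: no placement exists
        truth = SimTruth(seed=0, n_genes=5, seq_length=12, planted_units=6,
                         repeat_prevalence={"CTG": 1.0})
        with pytest.raises((RuntimeError, ValueError)):
            simulate_transcripts(truth, max_attempts=3)


class TestCounts:
    def test_shapes_labels_and_truth(self, default_truth, default_labels):
        sim = simulate_counts(default_truth, default_labels, n_case=5, n_control=4)
        cm = sim.counts
        assert cm.counts.shape == (default_truth.n_genes, 9)
        assert (cm.condition == "case").sum() == 5
        assert cm.phenotype is not None
        assert set(sim.gene_truth["direction"]) <= {"up", "down", "ns"}
        assert (sim.gene_truth.loc[~sim.gene_truth["is_de"], "log2fc"] == 0).all()

    def test_down_bias_on_repeat_genes(self):
        truth = SimTruth(seed=1, n_genes=5000, repeat_prevalence={"CTG": 0.3},
                         rho={"CTG": 3.0}, silencing_bias=0.8)
        sim = simulate_counts(truth, n_case=2, n_control=2)
        gt = sim.gene_truth
        rep_de = gt[(gt["motif"] == "CTG") & gt["is_de"]]
        other_de = gt[gt["motif"].isna() & gt["is_de"]]
        assert (rep_de["direction"] == "down").mean() > 0.7
        assert abs((other_de["direction"] == "down").mean() - 0.5) < 0.15

    def test_closed_form_ratio(self):
        truth = SimTruth(seed=0, repeat_prevalence={"CTG": 0.1}, rho={"CTG": 3.0}, pi0=0.05)
        assert truth.expected_enrichment_ratio() == pytest.approx(3 / (0.1 * 3 + 0.9))
        null = SimTruth(seed=0, rho={"CTG": 1.0})
        assert null.expected_enrichment_ratio() == pytest.approx(1.0)
        # DE probability caps at 1: P(DE|rep)=1, P(DE)=0.1*1+0.9*0.5
        capped = SimTruth(seed=0, pi0=0.5, rho={"CTG": 10.0})
        assert capped.expected_enrichment_ratio() == pytest.approx(1.0 / 0.55)

    def test_severity_links_phenotype(self, default_truth, default_labels):
        sim = simulate_counts(default_truth, default_labels, n_case=20, n_control=10)
        r = np.corrcoef(sim.severity, 1.0 - sim.counts.phenotype)[0, 1]
        assert r > 0.9

    def test_rejects_tiny_groups(self, default_truth):
        with pytest.raises(ValueError):
            simulate_counts(default_truth, n_case=1, n_control=5)


class TestTFAndSets:
    def test_preset_validation(self):
        with pytest.raises(ValueError, match="unknown preset"):
            preset_truth("nope", 0)
        assert preset_truth("null", 3).pi0 == 0.0

    def test_tf_table_unique_ranks_and_sig_fraction(self, default_truth, default_labels):
        table, net, _ = simulate_tf_table(default_truth, default_labels, n_tf=100)
        assert table["rank"].is_unique
        assert table["significant"].sum() == 60
        assert len(net.edges) == len(net.edges.drop_duplicates())

    def test_gene_sets_roundtrip_gmt(self, tmp_path, default_truth, default_labels):
        from tritarget.io import read_gmt, write_gmt

        up = list(default_labels.index[:50])
        collection, enriched = simulate_gene_sets(default_truth, up, list(default_labels.index),
                                                  n_sets=10)
        path = tmp_path / "sets.gmt"
        write_gmt(collection, path)
        assert read_gmt(path) == collection
        assert enriched <= set(collection)


def test_write_cohort_roundtrips(tmp_path):
    from tritarget import io as tio

    truth = SimTruth(seed=2, n_genes=80, seq_length=400, n_case=4, n_control=3,
                     repeat_prevalence={"CTG": 0.1})
    paths = write_cohort(truth, tmp_path)
    records = tio.read_fasta(paths["fasta"])
    assert len(records) == 80
    cm = tio.load_count_matrix(paths["counts"], paths["samples"])
    assert cm.counts.shape == (80, 7)
    assert cm.phenotype is not None
    regenerated = simulate_counts(truth, assign_repeat_labels(truth))
    assert cm.counts.equals(regenerated.counts.counts)
    assert "expected_enrichment_ratio_ctg" in truth_to_json(truth)
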