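# tritarget

Analysis toolkit for detecting transcriptome-wide dysregulation of genes
bearing endogenous trinucleotide repeats in case/control RNA-seq cohorts,
motivated by myotonic dystrophy type 1 (DM1). In DM1, expanded CTG repeats
in the DMPK 3′UTR are transcribed bidirectionally into CUG(n)/CAG(n) RNAs
that the RNAi machinery processes into ~18-nt repeat-derived siRNAs. Genes
whose own transcripts carry complementary runs — six CTG or CAG units is
~18 nt — are putative silencing targets, so the disease signature should
be enriched for repeat-bearing genes, transcription factors included.

`tritarget` implements the full analysis chain as a tested library + CLI:

- **repeat scanning** — phase-free detection of ≥k consecutive units of a
  3-mer motif (and its reverse complement) with up to m mismatches per
  3k-window, cataloged per gene over a motif × length grid;
- **differential expression** — CPM>1 expression filter, TMM
  normalization, log2-CPM, a variance-moderated two-sample t test
  (moderated-t surrogate for limma-voom), Benjamini–Hochberg FDR, and
  up/down calls at fold-change thresholds;
- **enrichment** — the core statistic: for each motif/length/threshold/
  direction cell, the observed number of repeat-bearing DE genes divided
  by the count expected from their prevalence in the tissue-expressed
  background, with an exact Fisher p (integer hypergeometric summation)
  and BH adjustment, CTG/CAG cells adjusted separately from control
  motifs (CGG, CGT, GAA, GCG); plus hypergeometric over-representation
  against GMT gene-set collections;
- **TF regulation** — flagging of repeat-bearing transcription factors in
  a user-supplied (ChEA3-style) ranking, an exact two-sample
  Kolmogorov–Smirnov test that carriers occupy better ranks, and
  coverage of the DE set through repeat-bearing TFs in a TF→gene network;
- **cohort structure & phenotype** — sample PCA, UPGMA heatmap ordering,
  Venn-style cross-cohort overlap with a replication test for repeat
  genes, and per-gene Pearson correlation with a clinical score
  (e.g. normalized dorsiflexion strength);
- **synthetic cohorts** — a negative-binomial generator that plants the
  assumed silencing structure (repeat carriers preferentially
  downregulated in proportion to per-patient severity) with full truth
  records, used by the test suite and reproducibility script.

## The core statistic

For a motif spec (unit u, ≥k units, ≤m mismatches), background universe
B (genes expressed in the tissue), repeat carriers R ⊆ B and DE genes
D ⊆ B at a given threshold and direction:

    expected = |D| · |R| / |B|
    ratio    = |D ∩ R| / expected

with a Fisher exact p on the 2×2 table (DE/not × repeat/not) and BH-q
within each motif family. `ratio > 1` means repeat carriers are
over-represented among DE genes beyond their background prevalence.

## Worked example

```sh
tritarget simulate --preset tibialis-like --seed 7 --out cohort/
cat > config.yaml <<EOF
fasta: cohort/transcripts.fasta
counts: cohort/counts.tsv
samples: cohort/samples.tsv
tf_ranks: cohort/tf_ranks.tsv
tf_edges: cohort/tf_edges.tsv
gene_sets: cohort/gene_sets.gmt
out_dir: results/
seed: 7
EOF
tritarget run --config config.yaml
```

The run writes `catalog.tsv`, `de_table.tsv`, `enrichment_grid.tsv`,
`tf_ks.json`, `phenotype_correlation.tsv` and friends under `results/`.
On this preset (40 cases / 10 controls, 2000 genes, CTG carriers planted
at prevalence 0.10 with relative DE risk 3) the CTG/CAG k=6 cell at
fold-change 1 prints, e.g.:

```
unit  k  m  direction  fc_threshold  n_de_repeat  n_de  ratio    q
CTG   6  0  both       1.0           25           110   2.28     0.00016
```

i.e. 25 repeat-bearing genes among 110 DE genes where ~11 were expected —
an observed/expected ratio of ≈2.3 against the planted closed-form value
of 2.5 — while the same cells for CGG/CGT/GAA/GCG stay at ratio ≈1 and
q > 0.05. `tf_ks.json` reports the one-sided KS p that repeat-bearing TFs
rank high, and `phenotype_correlation.tsv` the per-gene correlation with
the severity-linked phenotype score.

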