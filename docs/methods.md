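# Methods

## Repeat scanning

A motif spec is a 3-mer unit (paired by default with its reverse
complement, e.g. CTG↔CAG), a minimum unit count k ≥ 2 and a per-window
mismatch budget m ≤ 3k−1. A 3k-nucleotide window qualifies if its Hamming
distance to k tandem copies of *any cyclic rotation* of either paired
unit is ≤ m; rotation closure makes the scan phase-free, as an
alignment-based search would be. Equivalently, the rotation minimum at
start i equals the minimum over the three phase tilings of the unit,
which the scanner exploits with cumulative mismatch sums (O(sequence)
per unit and k). `N` never matches a motif base; any other non-ACGT
character is rejected with the offending position.

Overlapping qualifying windows of the same matched unit merge into one
maximal run reporting the whole units covered by the union (the union
length is floored to a multiple of 3) and the minimal mismatch count of
any member window; when both paired units produce an identical
(start, length) run, the lexicographically smaller unit is kept.
Coordinates are 0-based half-open everywhere.

Two consequences worth knowing:

- "k repeats" means *at least* k consecutive units: a 7-run is a member
  of the k=6 catalog, so gene sets shrink weakly in k and grow weakly in
  m.
- Rotation closure identifies motifs that are cyclic rotations of each
  other: CGG and GCG generate the same window family, hence identical
  gene sets. Both names are accepted; alignment-anchored searches that
  distinguish them will count differently.

Defaults follow the common usage for CTG/CAG: exact matching for k ∈
{4,5} and m = 2 for k ∈ {6,7}. No UTR/CDS distinction is made — hit
positions are recorded, but no region filter is applied.

## Differential expression

Gene-level counts are filtered by the rule "CPM > 1 in every sample of
at least one condition"; the alternative both-conditions reading would
discard exactly the condition-specific (e.g. strongly silenced) genes the
analysis is about. TMM factors follow the standard trimmed-mean-of-M
definition: reference = sample whose 75th-percentile CPM is closest to
the mean of those percentiles; M and A computed on library-normalized
abundances with zeros excluded; 30% trim per M tail and 5% per A tail;
inverse delta-method (Poisson) variance weights; factors rescaled to
geometric mean 1. Because M is computed on abundances, scaling a
sample's counts moves its library size, not its factor — the factor is a
pure composition adjustment and the effective library is
`lib_size × factor`.

Expression is log2-CPM with a fixed 0.5 prior:
`log2((count + 0.5) / (lib·factor + 1) · 1e6)`. The fixed prior makes
"double everything" invariance approximate, with an O(prior/count)
deviation (about 3×10⁻⁴ log2 units at count 1000).

The test is a moderated two-sample t per gene: pooled variance s²_g with
d_g = n₁+n₂−2 df shrunk toward s₀² (the median pooled variance) with
prior df d₀ = 4,

    s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),  t_g referred to t(d₀+d_g).

This is a deliberately simple surrogate for limma-voom's empirical-Bayes
moderation — no precision weights, no mean-variance trend — and is
documented as such; externally produced DE tables (gene, logFC, p, q)
can be injected via `io.read_de_table` / the `de_table` config key when
exact limma output is wanted. Under fully null NB cohorts (2000 genes,
10v10) the surrogate's raw p-values are uniform by KS at the 0.01 level
and <0.01% of genes pass BH at 0.05 (measured by the acceptance suite).
logFC is the difference of group-mean log-CPMs, matching the
fold-change-threshold semantics of the classifier (`up` iff q < α and
logFC ≥ log2 threshold; threshold 1 recovers significance-only calls).
BH is the literal step-up procedure.

## Cohort structure

Sample PCA runs on gene-wise mean-centered log-CPM via SVD; each
component's largest-magnitude gene loading is made positive so signs are
reproducible. Heatmap genes default to the top 100 |PC1| loadings (k
configurable). UPGMA is scipy's average linkage; the default distance is
Euclidean on row-z-scored log-CPM, with correlation distance as an
option (the choice is display-level; no statistic depends on it).

## Enrichment

Each grid cell is a 2×2 Fisher table (DE/not × repeat-bearing/not) on
the background of genes surviving the expression filter — "prevalence in
the tissue" is read as the tissue-expressed universe, not the whole
catalog; the whole-catalog background remains available by passing it
explicitly. The expected count is n_de·n_repeat_bg/n_bg and the ratio is
observed/expected. p-values are computed by exact integer hypergeometric
point-probability summation (numerators over a common denominator), so
the two-sided "sum of probabilities ≤ observed" rule needs no
floating-point tie slack; two-sided is the default (enrichment among
both up- and downregulated genes is a finding, not a nuisance), one-sided
is available. BH runs within the CTG/CAG family separately from the
control-motif family (CGG, CGT, GAA, GCG), so control cells cannot dilute
the primary test. The "at least two DE repeat genes" rule sets a
`displayable` flag used only by the bar-chart output; statistics are
never dropped.

ORA against GMT collections is one-sided hypergeometric upper-tail per
set (sets intersected with the background; < 3 members skipped), BH
across the collection.

## TF rank test and network coverage

The upstream TF-target enrichment engine is consumed, not reimplemented:
inputs are a ranked TF table (ranks unique; a `significant` flag or an
`fdr` column thresholded at 0.01 defines the tested universe) and an
edge table. Carriers are TFs in the CTG/CAG catalog at k=6 (m≤2 by
default); TFs absent from the catalog background are excluded from the
test with a logged count. The KS statistic compares rank distributions
of carriers vs the rest; the default alternative is one-sided toward
better (smaller) ranks, since the hypothesis is directional. With
distinct ranks there are no ties, and the null distribution is computed
*exactly* by integer lattice-path counting (O(mn) dynamic program over
interleavings) whenever m·n ≤ 10⁶, otherwise by the asymptotic
one-sided tail exp(−2D²mn/(m+n)). Coverage is the fraction of DE genes
with ≥1 incoming edge from a carrier TF, reported overall and per
direction with per-TF out-degrees.

## Cross-cohort replication

Venn counts partition the union of DE genes by the number of cohorts
calling them (overall and for the repeat-bearing subset). The
replication test asks whether the reference cohort's repeat-bearing DE
genes appear DE in ≥1 other cohort more often than its remaining DE
genes: a one-sided Fisher test on the 2×2 (carrier/remaining ×
replicates/not). Overlap is direction-agnostic by default (up- and
downregulated genes are pooled); a direction-matched mode exists.

## Synthetic cohorts

The generator emulates the statistical structure of a tibialis-like
case/control cohort; its defaults are the package's study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | gene universe |
| repeat_prevalence | CTG 0.10 | fraction of genes given a planted run |
| planted_units / mismatches | 6 / 0 | exact 18-nt run per carrier |
| seq_length | 1500 nt | transcript length |
| pi0 | 0.05 | DE probability, non-repeat genes |
| rho | CTG 3.0 | DE relative risk for carriers, capped so ρ·π₀ ≤ 1 |
| silencing_bias δ | 0.7 | P(down \| DE, carrier); others 1/2 |
| \|log2FC\| | N(1.5, 0.4), ≥ 0.25 | planted effect size |
| baseline log2 mean | N(5, 2) | ~32 counts typical, heavy right tail |
| NB dispersion | LogNormal(ln 0.1, 0.6) | realistic bulk overdispersion |
| severity | U(0.3, 1) cases, 0 controls | scales each case's planted shift |
| phenotype | 1 − severity + N(0, 0.1) | strength-score analogue |
| library sizes | U(8×10⁵, 1.2×10⁶) | down-scaled sequencing depth |
| cohort size | 40 cases / 10 controls | tibialis-like preset |

Case sample s expresses DE gene g at log2 mean μ_g + severity_s·log2FC_g,
columns are rescaled to the drawn library sizes, and counts are sampled
NB(mean, dispersion). Background transcript sequences are i.i.d. uniform
DNA rejection-resampled against the scanner itself so they contain no
qualifying run on the k∈{4..7} × m∈{0,2} grid for any planted motif
family; planted genes get exactly one run at a uniform position and are
re-screened so they match no *other* family. This trades generation speed
for an exact label/catalog correspondence: at any spec with k ≤ planted
units and m ≥ planted mismatches the scan recovers exactly the planted
set. The closed-form enrichment ratio implied by the planted parameters,

    ratio = P(DE | carrier) / P(DE) = min(1, ρπ₀) / (Σ prevᵤ·min(1, ρᵤπ₀) + (1−Σ prevᵤ)·π₀),

is emitted with each cohort and is what the recovery checks compare
against (2.5 at the defaults).

TF tables draw a 0.3 fraction of TFs from planted carriers; latent
scores are U(0,1) for the rest and U(0,1) − bias for carriers (bias 0 is
an exchangeable null, bias ≥ 1 puts all carriers on top; default 0.8),
and ranks order the scores. Networks are wired so that exactly
round(coverage·|DE|) DE genes receive a carrier edge (default 0.5), with
carrier background edges restricted to covered or non-DE genes so the
planted coverage is exact. Gene-set collections over-sample planted
up-genes with odds 10 in 30% of sets.

Multi-tissue simulation (`simulate_multi_cohort`) draws the carriers' DE
effects **once** and reuses them in every cohort — the repeat-siRNA
mechanism targets the same carrier transcripts in every tissue — while
non-repeat DE (downstream, tissue-specific regulation) and all baselines
are redrawn per cohort. This is what makes carrier DE genes replicate
across tissues more than the rest, and it is the planted structure the
replication test is validated against.

Named presets: `tibialis-like` (defaults plus control motifs CGG 0.05,
CGT 0.02, GAA 0.04, GCG 0.05), `specificity` (all five motifs at matched
prevalence 0.05, silencing ρ=5 on CTG/CAG carriers only — a clearly
detectable planted effect at 20v10), and `null` (π₀ = 0). All
randomness flows from a single integer seed through named substreams;
identical seeds give bit-identical outputs.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes —
NB-distributed counts with library-size and composition effects,
carrier-biased DE, severity-linked effects and phenotype, rank-biased TF
tables, exactly-wired network coverage. It does not model read-level
noise, splicing (MBNL-dependent or otherwise), gene–gene correlation
beyond compositional coupling, batch structure, covariates such as age
or sex, or real repeat-length polymorphism. Passing tests therefore
demonstrate that the statistics recover planted effects of realistic
size under idealized sampling, not that any particular biological cohort
satisfies those assumptions.

## Numerical and scale choices

- Exact integer arithmetic for Fisher and KS null distributions removes
  tie-breaking ambiguity; p-values are clipped to (tiny, 1].
- Moderated-variance degrees of freedom, the 0.5 prior count, α = 0.05
  and the 1.5-fold threshold are exposed as configuration.
- Validation cohorts run at 20 cases / 10 controls with 2000 genes (the
  tibialis-like preset keeps 40v10); sequence-level steps use 1500-nt
  transcripts. These sizes keep every property measurable with
  comfortable margins while the whole suite stays quick.
- Degenerate inputs signal rather than guess: empty post-filter
  matrices, constant expression for PCA, NaN distances for UPGMA,
  all-carrier TF tables, empty replication partitions.

## Known limitations

- The moderated t is not limma-voom; cohorts with strong mean-variance
  trends or precision differences between samples are better served by
  injecting an external DE table.
- The scanner's rotation closure cannot distinguish motifs that are
  rotations of each other (CGG vs GCG).
- GSEA's running-sum statistic, upstream TF-enrichment engines and
  curated pathway/miRNA databases are out of scope; gene sets and TF
  rankings are inputs.
- Phenotype correlation treats scores as given and models no covariates.
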