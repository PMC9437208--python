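"""Synthetic cohorts with planted repeat-silencing structure.

The generator emulates the statistical structure the analysis assumes: a
case/control negative-binomial count matrix in which a subset of genes
carries planted CTG/CAG (or control-motif) repeat runs and is
preferentially dysregulated — down-biased, in proportion to per-patient
severity — together with transcript FASTA, phenotype scores, TF ranking
tables, TF->gene networks and gene-set collections. Every planted
parameter is recorded in a :class:`SimTruth`, and the closed-form
enrichment ratio implied by the planted prevalence and relative risk is
emitted alongside each cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .de import CASE, CONTROL, CountMatrix
from .repeat_scan import MotifSpec, build_catalog, rotation_family, scan_sequence
from .tf import RegulatoryNetwork

__all__ = [
    "SimTruth",
    "SimulatedCohort",
    "assign_repeat_labels",
    "expected_catalog",
    "simulate_transcripts",
    "simulate_counts",
    "simulate_tf_table",
    "simulate_gene_sets",
    "preset_truth",
    "write_cohort",
]

# rng stream ids, one per generator stage, spawned from the master seed
_STREAM_LABELS = 1
_STREAM_SEQS = 2
_STREAM_COUNTS = 3
_STREAM_TF = 4
_STREAM_SETS = 5


@dataclass(frozen=True)
class SimTruth:
    """All planted parameters of one synthetic cohort.

    ``repeat_prevalence`` maps motif units to the fraction of genes given a
    planted run of that motif; ``rho`` maps motif units to the relative
    risk of differential expression for their carriers (motifs absent from
    ``rho`` behave like non-repeat genes). ``pi0`` is the DE probability
    of a non-repeat gene and ``silencing_bias`` the probability that a DE
    repeat gene is downregulated. Case severities scale the planted log2
    fold changes and generate the phenotype y = 1 - severity + noise.
    """

    seed: int
    n_genes: int = 2000
    repeat_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {"CTG": 0.10}
    )
    rho: Mapping[str, float] = field(default_factory=lambda: {"CTG": 3.0})
    pi0: float = 0.05
    silencing_bias: float = 0.7
    planted_units: int = 6
    planted_mismatches: int = 0
    seq_length: int = 1500
    baseline_log2_mean: tuple[float, float] = (5.0, 2.0)
    dispersion_lognorm: tuple[float, float] = (float(np.log(0.1)), 0.6)
    effect_size: tuple[float, float] = (1.5, 0.4)
    effect_size_min: float = 0.25
    severity_range: tuple[float, float] = (0.3, 1.0)
    phenotype_noise: float = 0.1
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    tf_rank_bias: float = 0.8
    tf_repeat_fraction: float = 0.3
    tf_significant_fraction: float = 0.6
    network_target_coverage: float = 0.5
    n_case: int = 40
    n_control: int = 10

    def __post_init__(self) -> None:
        probs = [self.pi0, self.silencing_bias, *self.repeat_prevalence.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if sum(self.repeat_prevalence.values()) > 1:
            raise ValueError("total planted prevalence exceeds 1")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def de_probability(self, motif: str | None) -> float:
        r = self.rho.get(motif, 1.0) if motif else 1.0
        return min(1.0, r * self.pi0)

    def expected_enrichment_ratio(self, unit: str = "CTG") -> float:
        """Closed-form observed/expected ratio implied by the planted
        prevalences and relative risks: P(DE | carrier of ``unit``'s
        rotation family) / P(DE)."""
        fam = rotation_family(unit)
        p_de_total = 0.0
        remaining = 1.0
        p_de_unit = self.pi0
        for motif, prev in self.repeat_prevalence.items():
            p = self.de_probability(motif)
            p_de_total += prev * p
            remaining -= prev
            if rotation_family(motif) == fam:
                p_de_unit = p
        p_de_total += remaining * self.pi0
        if p_de_total == 0:
            return float("nan")  # no DE at all: ratio undefined
        return p_de_unit / p_de_total


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def assign_repeat_labels(truth: SimTruth) -> pd.Series:
    """Assign each gene at most one planted motif (or None), reproducibly.

    Counts per motif are round(prevalence * n_genes); assignment is a
    seeded permutation of the gene universe.
    """
    rng = truth.rng(_STREAM_LABELS)
    genes = _gene_ids(truth.n_genes)
    labels = pd.Series([None] * truth.n_genes, index=genes, dtype=object, name="motif")
    perm = rng.permutation(truth.n_genes)
    pos = 0
    for motif in sorted(truth.repeat_prevalence):
        n_m = round(truth.repeat_prevalence[motif] * truth.n_genes)
        labels.iloc[perm[pos : pos + n_m]] = motif
        pos += n_m
    return labels


def expected_catalog(truth: SimTruth, labels: pd.Series, spec: MotifSpec) -> frozenset[str]:
    """The planted gene set a scan at ``spec`` must recover.

    Exact when ``spec.min_units <= planted_units`` and
    ``spec.max_mismatches >= planted_mismatches`` (transcript generation
    rejection-screens every other qualifying run); for larger k the
    planted run cannot guarantee membership.
    """
    if spec.min_units > truth.planted_units or spec.max_mismatches < truth.planted_mismatches:
        raise ValueError(f"planted runs do not determine membership at {spec.label()}")
    return frozenset(
        g
        for g, motif in labels.items()
        if motif is not None and rotation_family(motif) == spec.family
    )


def _screening_specs(truth: SimTruth) -> list[MotifSpec]:
    """Minimal spec set whose emptiness implies no hit anywhere on the
    k in {4..7} x m in {0,2} grid: (k=4, m=0) and (k=6, m=2) per family."""
    specs: list[MotifSpec] = []
    seen: set[frozenset[str]] = set()
    units = set(truth.repeat_prevalence) | {"CTG"}
    for unit in sorted(units):
        fam = rotation_family(unit)
        if fam in seen:
            continue
        seen.add(fam)
        specs.append(MotifSpec(unit, min_units=4, max_mismatches=0))
        specs.append(MotifSpec(unit, min_units=6, max_mismatches=2))
    return specs


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _plant_run(truth: SimTruth, motif: str, rng: np.random.Generator) -> str:
    run = list(motif * truth.planted_units)
    if truth.planted_mismatches:
        pos = rng.choice(len(run), size=truth.planted_mismatches, replace=False)
        for p in pos:
            alts = [b for b in "ACGT" if b != run[p]]
            run[p] = alts[rng.integers(0, 3)]
    return "".join(run)


def simulate_transcripts(
    truth: SimTruth, labels: pd.Series | None = None, max_attempts: int = 200
) -> tuple[list[tuple[str, str]], pd.Series]:
    """Transcript FASTA records with planted runs and clean backgrounds.

    Background sequences are uniform i.i.d. DNA rejection-resampled
    against the scanner so they contain no qualifying run of any planted
    (or CTG/CAG) motif family on the k in {4..7}, m in {0,2} grid; planted
    genes carry exactly one run of their motif at a uniform position.
    """
    if labels is None:
        labels = assign_repeat_labels(truth)
    rng = truth.rng(_STREAM_SEQS)
    specs = _screening_specs(truth)
    own_fams = {unit: rotation_family(unit) for unit in set(truth.repeat_prevalence) | {"CTG"}}
    records: list[tuple[str, str]] = []
    for gene_id, motif in labels.items():
        for attempt in range(max_attempts):
            seq = _random_seq(rng, truth.seq_length)
            if motif is not None:
                run = _plant_run(truth, motif, rng)
                pos = int(rng.integers(0, truth.seq_length - len(run) + 1))
                seq = seq[:pos] + run + seq[pos + len(run):]
            ok = True
            for spec in specs:
                hits = scan_sequence(seq, spec)
                if motif is not None and spec.family == own_fams[motif]:
                    if spec.max_mismatches >= truth.planted_mismatches and not hits:
                        ok = False  # planted run failed to register (should not happen)
                        break
                elif hits:
                    ok = False
                    break
            if ok:
                records.append((gene_id, seq))
                break
        else:
            raise RuntimeError(
                f"could not generate a clean sequence for {gene_id} in {max_attempts} attempts; "
                "configuration infeasible (sequence too short or budget too permissive?)"
            )
    return records, labels


@dataclass
class SimulatedCohort:
    """A synthetic count cohort plus its per-gene truth."""

    counts: CountMatrix
    gene_truth: pd.DataFrame  # motif, is_de, direction, log2fc
    severity: pd.Series
    truth: SimTruth


def draw_gene_effects(truth: SimTruth, labels: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Per-gene baseline, dispersion and planted DE effect.

    DE indicator with probability pi0 (non-repeat) or min(1, rho*pi0)
    (repeat carriers of motifs listed in ``rho``); DE repeat genes are
    downregulated with probability ``silencing_bias`` (1/2 otherwise);
    |log2FC| ~ Normal(truth.effect_size) clipped below.
    """
    n = truth.n_genes
    mu = rng.normal(*truth.baseline_log2_mean, size=n)
    disp = rng.lognormal(*truth.dispersion_lognorm, size=n)
    p_de = np.array([truth.de_probability(m) for m in labels], dtype=float)
    is_de = rng.random(n) < p_de
    has_rho = np.array([m is not None and m in truth.rho for m in labels])
    p_down = np.where(has_rho, truth.silencing_bias, 0.5)
    down = rng.random(n) < p_down
    lfc_abs = np.maximum(rng.normal(*truth.effect_size, size=n), truth.effect_size_min)
    lfc = np.where(is_de, np.where(down, -lfc_abs, lfc_abs), 0.0)
    return pd.DataFrame(
        {"mu": mu, "disp": disp, "is_de": is_de, "down": down, "log2fc": lfc,
         "targeted": has_rho},
        index=labels.index,
    )


def simulate_counts(
    truth: SimTruth,
    labels: pd.Series | None = None,
    n_case: int | None = None,
    n_control: int | None = None,
    gene_effects: pd.DataFrame | None = None,
    stream_key: int = 0,
) -> SimulatedCohort:
    """Negative-binomial case/control counts with planted DE structure.

    Per gene: baseline log2 mean ~ Normal(truth.baseline_log2_mean), NB
    dispersion ~ LogNormal(truth.dispersion_lognorm); DE effects per
    :func:`draw_gene_effects` (or injected via ``gene_effects``). Case
    sample s shifts DE genes by severity_s * log2FC; columns are scaled
    to uniform library sizes; the phenotype is
    1 - severity + Normal(0, phenotype_noise). ``stream_key`` separates
    cohorts drawn from the same truth (multi-tissue simulations).
    """
    if labels is None:
        labels = assign_repeat_labels(truth)
    n_case = truth.n_case if n_case is None else n_case
    n_control = truth.n_control if n_control is None else n_control
    if n_case < 2 or n_control < 2:
        raise ValueError("need at least 2 samples per condition")
    rng = truth.rng(_STREAM_COUNTS) if stream_key == 0 else np.random.default_rng(
        [truth.seed, _STREAM_COUNTS, stream_key]
    )
    n = truth.n_genes
    genes = list(labels.index)
    if gene_effects is None:
        gene_effects = draw_gene_effects(truth, labels, rng)
    mu = gene_effects["mu"].to_numpy()
    disp = gene_effects["disp"].to_numpy()
    is_de = gene_effects["is_de"].to_numpy()
    down = gene_effects["down"].to_numpy()
    lfc = gene_effects["log2fc"].to_numpy()
    severity = rng.uniform(*truth.severity_range, size=n_case)
    sample_ids = [f"ctrl{i + 1:02d}" for i in range(n_control)] + [
        f"case{i + 1:02d}" for i in range(n_case)
    ]
    sev_all = np.concatenate([np.zeros(n_control), severity])
    log2_mean = mu[:, None] + lfc[:, None] * sev_all[None, :]
    rel = 2.0 ** log2_mean
    lib = rng.uniform(*truth.lib_size_range, size=n_control + n_case)
    mean = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]
    r = 1.0 / disp[:, None]
    counts = rng.negative_binomial(r, r / (r + mean))
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        condition=pd.Series(
            [CONTROL] * n_control + [CASE] * n_case, index=sample_ids, name="condition"
        ),
        phenotype=pd.Series(
            1.0 - sev_all + rng.normal(0.0, truth.phenotype_noise, size=sev_all.size),
            index=sample_ids,
            name="phenotype",
        ),
    )
    gene_truth = pd.DataFrame(
        {
            "motif": labels.to_numpy(),
            "is_de": is_de,
            "direction": np.where(is_de, np.where(down, "down", "up"), "ns"),
            "log2fc": lfc,
        },
        index=genes,
    )
    gene_truth.index.name = "gene_id"
    return SimulatedCohort(
        counts=cm,
        gene_truth=gene_truth,
        severity=pd.Series(sev_all, index=sample_ids, name="severity"),
        truth=truth,
    )


def simulate_multi_cohort(
    truth: SimTruth,
    n_cohorts: int = 3,
    n_case: int | None = None,
    n_control: int | None = None,
    shared_repeat_effects: bool = True,
) -> tuple[list[SimulatedCohort], pd.Series]:
    """Cohorts from distinct tissues sharing the repeat-silencing signal.

    The repeat-derived siRNA mechanism targets the same carrier genes in
    every tissue, so with ``shared_repeat_effects`` the DE indicator,
    direction and effect size of repeat carriers are drawn once and reused
    across cohorts, while non-repeat DE (downstream, tissue-specific
    regulation) and all baselines are redrawn per cohort. Returns the
    cohorts and the shared labels.
    """
    if n_cohorts < 2:
        raise ValueError("need at least 2 cohorts")
    labels = assign_repeat_labels(truth)
    shared = draw_gene_effects(truth, labels, truth.rng(_STREAM_COUNTS))
    cohorts = []
    for c in range(n_cohorts):
        # effect draws live on a stream disjoint from the sampling stream
        rng_c = np.random.default_rng([truth.seed, _STREAM_COUNTS, c + 1, 1])
        effects = draw_gene_effects(truth, labels, rng_c)
        if shared_repeat_effects:
            mask = effects["targeted"].to_numpy()
            for col in ("is_de", "down", "log2fc"):
                effects.loc[mask, col] = shared.loc[mask, col]
        cohorts.append(
            simulate_counts(truth, labels, n_case=n_case, n_control=n_control,
                            gene_effects=effects, stream_key=c + 1)
        )
    return cohorts, labels


def simulate_tf_table(
    truth: SimTruth,
    labels: pd.Series | None = None,
    de_genes: Sequence[str] | None = None,
    n_tf: int = 100,
    bias: float | None = None,
    coverage: float | None = None,
) -> tuple[pd.DataFrame, RegulatoryNetwork, dict]:
    """Ranked TF table and TF->gene network with planted rank bias.

    A ``tf_repeat_fraction`` of TFs are drawn from planted CTG/CAG-family
    genes; latent scores are Uniform(0,1) for other TFs and
    Uniform(0,1) - bias for repeat TFs (bias 0 = exchangeable null, bias
    >= 1 puts carriers at the top ranks); ranks order the scores. Edges
    are wired so that exactly round(coverage * |DE|) DE genes receive an
    edge from a repeat-bearing TF.
    """
    if labels is None:
        labels = assign_repeat_labels(truth)
    if n_tf < 10:
        raise ValueError("need at least 10 TFs")
    bias = truth.tf_rank_bias if bias is None else bias
    coverage = truth.network_target_coverage if coverage is None else coverage
    rng = truth.rng(_STREAM_TF)
    ctg_fam = rotation_family("CTG")
    carriers = [g for g, m in labels.items() if m is not None and rotation_family(m) == ctg_fam]
    others_pool = [g for g, m in labels.items() if m is None]
    n_rep = round(truth.tf_repeat_fraction * n_tf)
    if n_rep > len(carriers) or n_tf - n_rep > len(others_pool):
        raise ValueError("not enough planted / plain genes to draw TFs from")
    rep_tfs = list(rng.choice(carriers, size=n_rep, replace=False))
    other_tfs = list(rng.choice(others_pool, size=n_tf - n_rep, replace=False))
    tf_ids = rep_tfs + other_tfs
    scores = np.concatenate([rng.random(n_rep) - bias, rng.random(n_tf - n_rep)])
    order = np.argsort(scores, kind="stable")
    rank = np.empty(n_tf, dtype=int)
    rank[order] = np.arange(1, n_tf + 1)
    n_sig = round(truth.tf_significant_fraction * n_tf)
    table = pd.DataFrame(
        {"tf_id": tf_ids, "rank": rank, "significant": rank <= n_sig}
    ).sort_values("rank", kind="mergesort").reset_index(drop=True)

    de = list(de_genes) if de_genes is not None else []
    edges: list[tuple[str, str]] = []
    covered: list[str] = []
    if de:
        n_cov = round(coverage * len(de))
        perm = rng.permutation(len(de))
        covered = [de[i] for i in perm[:n_cov]]
        uncovered = [de[i] for i in perm[n_cov:]]
        for g in covered:
            edges.append((rep_tfs[int(rng.integers(0, len(rep_tfs)))], g))
        for g in uncovered:
            edges.append((other_tfs[int(rng.integers(0, len(other_tfs)))], g))
    # background wiring: repeat TFs may only touch covered or non-DE genes,
    # so the planted coverage fraction is exact
    non_de = [g for g in labels.index if g not in set(de)]
    for tf in tf_ids:
        pool = covered + non_de if tf in set(rep_tfs) else list(labels.index)
        extra = rng.integers(2, 6)
        for g in rng.choice(pool, size=min(extra, len(pool)), replace=False):
            edges.append((tf, g))
    edge_df = pd.DataFrame(edges, columns=["tf_id", "gene_id"]).drop_duplicates().reset_index(drop=True)
    net = RegulatoryNetwork(edges=edge_df, repeat_tfs=frozenset(rep_tfs))
    return table, net, {"repeat_tfs": frozenset(rep_tfs), "covered_genes": frozenset(covered)}


def simulate_gene_sets(
    truth: SimTruth,
    up_genes: Sequence[str],
    universe: Sequence[str],
    n_sets: int = 50,
    frac_enriched: float = 0.3,
    odds: float = 10.0,
    size_range: tuple[int, int] = (20, 100),
) -> tuple[dict[str, frozenset[str]], frozenset[str]]:
    """GMT-style collection; a fraction of sets over-sample planted up-genes.

    Enriched sets draw members with weight ``odds`` for up-genes and 1
    otherwise (odds 1 = null); the returned truth names the enriched sets.
    """
    if n_sets < 1:
        raise ValueError("need at least one gene set")
    rng = truth.rng(_STREAM_SETS)
    universe = list(universe)
    up = set(up_genes)
    weights_enriched = np.array([odds if g in up else 1.0 for g in universe])
    weights_enriched /= weights_enriched.sum()
    n_enriched = round(frac_enriched * n_sets)
    collection: dict[str, frozenset[str]] = {}
    enriched_names: set[str] = set()
    for i in range(n_sets):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(universe))
        if i < n_enriched:
            members = rng.choice(universe, size=size, replace=False, p=weights_enriched)
            enriched_names.add(f"set{i:03d}")
        else:
            members = rng.choice(universe, size=size, replace=False)
        collection[f"set{i:03d}"] = frozenset(members)
    return collection, frozenset(enriched_names)


def preset_truth(name: str, seed: int) -> SimTruth:
    """Named study configurations.

    tibialis-like: 40 cases / 10 controls, CTG prevalence 0.10 plus
    control motifs at lower prevalence, rho=3 on CTG carriers.
    specificity: all five motifs planted at matched prevalence 0.05,
    silencing (rho=5) only on CTG/CAG carriers.
    null: no differential expression at all (pi0=0).
    """
    if name == "tibialis-like":
        return SimTruth(
            seed=seed,
            repeat_prevalence={"CTG": 0.10, "CGG": 0.05, "CGT": 0.02, "GAA": 0.04, "GCG": 0.05},
            rho={"CTG": 3.0},
        )
    if name == "specificity":
        return SimTruth(
            seed=seed,
            repeat_prevalence={u: 0.05 for u in ("CTG", "CGG", "CGT", "GAA", "GCG")},
            rho={"CTG": 5.0},
        )
    if name == "null":
        return SimTruth(seed=seed, pi0=0.0, rho={})
    raise ValueError(f"unknown preset {name!r}; choose tibialis-like, specificity or null")


def truth_to_json(truth: SimTruth) -> str:
    d = dataclasses.asdict(truth)
    d["repeat_prevalence"] = dict(d["repeat_prevalence"])
    d["rho"] = dict(d["rho"])
    ratio = truth.expected_enrichment_ratio("CTG")
    d["expected_enrichment_ratio_ctg"] = ratio if np.isfinite(ratio) else None
    return json.dumps(d, indent=2, sort_keys=True)


def write_cohort(truth: SimTruth, out_dir: str | Path, with_sequences: bool = True) -> dict[str, Path]:
    """Emit FASTA, counts TSV, sample sheet, TF tables, GMT and truth JSON."""
    from . import io as tio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = assign_repeat_labels(truth)
    paths: dict[str, Path] = {}
    if with_sequences:
        records, labels = simulate_transcripts(truth, labels)
        paths["fasta"] = out / "transcripts.fasta"
        tio.write_fasta(records, paths["fasta"])
    cohort = simulate_counts(truth, labels)
    paths["counts"] = out / "counts.tsv"
    tio.write_counts(cohort.counts, paths["counts"])
    paths["samples"] = out / "samples.tsv"
    tio.write_sample_sheet(cohort.counts, paths["samples"])
    paths["gene_truth"] = out / "gene_truth.tsv"
    tio.write_table(cohort.gene_truth.reset_index(), paths["gene_truth"])
    de_true = list(cohort.gene_truth.index[cohort.gene_truth["is_de"]])
    # scale the TF universe to what the planted carrier pool can supply
    ctg_fam = rotation_family("CTG")
    n_carriers = sum(1 for m in labels if m is not None and rotation_family(m) == ctg_fam)
    n_plain = int(labels.isna().sum())
    n_tf = min(
        100,
        int(n_carriers / max(truth.tf_repeat_fraction, 1e-9)),
        int(n_plain / max(1.0 - truth.tf_repeat_fraction, 1e-9)),
    )
    n_tf = max(n_tf, 10)
    tf_table, net, _ = simulate_tf_table(truth, labels, de_genes=de_true, n_tf=n_tf)
    paths["tf_ranks"] = out / "tf_ranks.tsv"
    tio.write_table(tf_table, paths["tf_ranks"])
    paths["tf_edges"] = out / "tf_edges.tsv"
    tio.write_table(net.edges, paths["tf_edges"])
    up_true = list(cohort.gene_truth.index[cohort.gene_truth["direction"] == "up"])
    collection, _ = simulate_gene_sets(truth, up_true, list(labels.index))
    paths["gene_sets"] = out / "gene_sets.gmt"
    tio.write_gmt(collection, paths["gene_sets"])
    paths["truth"] = out / "truth.json"
    paths["truth"].write_text(truth_to_json(truth) + "\n")
    return paths
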