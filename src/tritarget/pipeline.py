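"""Pipeline orchestration: scan -> DE -> structure -> enrichment -> TF -> phenotype.

A single declarative config (YAML, flat keys; unknown keys rejected)
drives all stages; every output table carries a header comment with the
package version, a config hash and the seed, and a partial failure leaves
completed outputs plus a machine-readable ``error.json``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__, io as tio
from .de import EmptyResultError, run_de
from .enrichment import enrichment_grid, ora_gene_sets
from .phenotype import gene_phenotype_correlation
from .repeat_scan import MotifSpec, build_catalog, catalog_summary, hits_table, scan_transcripts
from .structure import Dendrogram, pca_samples, top_loading_genes, upgma_linkage, zscore_rows
from .tf import DEFAULT_TF_SPEC, flag_repeat_tfs, ks_rank_test, network_coverage, RegulatoryNetwork

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    def __init__(self, message: str, exit_code: int = 1):
        super().__init__(message)
        self.exit_code = exit_code


class PipelineConfig(BaseModel):
    """Declarative pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    fasta: str
    counts: str
    samples: str
    out_dir: str = "results"
    units: list[str] = ["CTG", "CGG", "CGT", "GAA", "GCG"]
    ks: list[int] = [4, 5, 6, 7]
    mismatches: list[int] = [0, 0, 2, 2]
    include_complement: bool = True
    fc_thresholds: list[float] = [1.0, 1.5, 2.0]
    alpha: float = 0.05
    min_cpm: float = 1.0
    d0: float = 4.0
    prior_count: float = 0.5
    heatmap_genes: int = 100
    cluster_metric: Literal["euclidean", "correlation"] = "euclidean"
    fisher_alternative: Literal["two-sided", "greater"] = "two-sided"
    tf_ranks: str | None = None
    tf_edges: str | None = None
    tf_fdr_threshold: float = 0.01
    ks_alternative: Literal["less", "two-sided"] = "less"
    gene_sets: str | None = None
    de_table: str | None = None
    plots: bool = False
    seed: int = 0
    threads: int = 1

    @field_validator("ks")
    @classmethod
    def _ks_positive(cls, v):
        if any(k < 2 for k in v):
            raise ValueError("repeat lengths must be >= 2")
        return v

    @field_validator("fc_thresholds")
    @classmethod
    def _fc_valid(cls, v):
        if any(t < 1 for t in v):
            raise ValueError("fold-change thresholds must be >= 1")
        return v

    def motif_specs(self) -> list[MotifSpec]:
        if len(self.ks) != len(self.mismatches):
            raise ValueError("ks and mismatches must have equal length")
        return [
            MotifSpec(unit, k, m, self.include_complement)
            for unit in self.units
            for k, m in zip(self.ks, self.mismatches)
        ]

    def digest(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise PipelineError(f"config {path} is not a mapping", exit_code=2)
    raw.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig(**raw)
    except Exception as exc:
        raise PipelineError(f"invalid config: {exc}", exit_code=2) from exc


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every configured stage in dependency order.

    Returns the output directory. Stage outputs already written survive a
    failure, alongside ``error.json`` naming the failed stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = [
        f"tritarget {__version__}",
        f"config_hash {config.digest()}",
        f"seed {config.seed}",
    ]
    stage = "setup"
    try:
        for name, path in (("fasta", config.fasta), ("counts", config.counts),
                           ("samples", config.samples), ("tf_ranks", config.tf_ranks),
                           ("tf_edges", config.tf_edges), ("gene_sets", config.gene_sets),
                           ("de_table", config.de_table)):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"missing input file for {name}: {path}", exit_code=3)

        stage = "scan"
        logger.info("stage scan: cataloging repeats")
        transcripts = tio.read_fasta(config.fasta)
        specs = config.motif_specs()
        catalog = build_catalog(transcripts, specs)
        tio.write_catalog(catalog, out / "catalog.tsv", header)
        tio.write_table(catalog_summary(catalog), out / "catalog_summary.tsv", header)
        hits = scan_transcripts(transcripts, specs)
        tio.write_table(
            pd.concat([hits_table(h) for h in hits.values()], ignore_index=True),
            out / "repeat_hits.tsv", header,
        )

        stage = "de"
        logger.info("stage de: differential expression")
        cm = tio.load_count_matrix(config.counts, config.samples)
        try:
            filtered, nm, det = run_de(
                cm, fc_threshold=1.5, alpha=config.alpha, d0=config.d0,
                min_cpm=config.min_cpm, prior_count=config.prior_count,
            )
        except EmptyResultError as exc:
            raise PipelineError(str(exc), exit_code=4) from exc
        if config.de_table:
            det = tio.read_de_table(config.de_table)
            logger.info("injected external DE table from %s", config.de_table)
        tio.write_table(det.reset_index(), out / "de_table.tsv", header)
        logdf = nm.logcpm.copy()
        logdf.index.name = "gene_id"
        tio.write_table(logdf.reset_index(), out / "logcpm.tsv", header)
        tio.write_table(
            pd.DataFrame({"sample_id": nm.lib_size.index, "lib_size": nm.lib_size.values,
                          "tmm_factor": nm.tmm_factor.values}),
            out / "normalization.tsv", header,
        )

        stage = "structure"
        logger.info("stage structure: PCA and UPGMA")
        emb = pca_samples(nm)
        coords = emb.coords.copy()
        coords.index.name = "sample_id"
        tio.write_table(coords.reset_index(), out / "pca_samples.tsv", header)
        top = top_loading_genes(emb, n=config.heatmap_genes)
        z = zscore_rows(nm.logcpm.loc[top])
        gene_dend = upgma_linkage(z, axis="rows", metric=config.cluster_metric)
        sample_dend = upgma_linkage(z, axis="columns", metric=config.cluster_metric)
        ordered = z.loc[gene_dend.leaf_order, sample_dend.leaf_order]
        ordered.index.name = "gene_id"
        tio.write_table(ordered.reset_index(), out / "heatmap_matrix.tsv", header)
        for name, dend in (("genes", gene_dend), ("samples", sample_dend)):
            link = pd.DataFrame(dend.linkage, columns=["node_a", "node_b", "height", "size"])
            tio.write_table(link, out / f"linkage_{name}.tsv", header)

        stage = "enrich"
        logger.info("stage enrich: repeat-gene enrichment grid")
        grid = enrichment_grid(
            det, catalog, fc_thresholds=config.fc_thresholds, alpha=config.alpha,
            alternative=config.fisher_alternative,
        )
        tio.write_table(grid, out / "enrichment_grid.tsv", header)
        if config.gene_sets:
            collection = tio.read_gmt(config.gene_sets)
            background = set(det.index)
            from .de import classify_de, de_sets
            sets = de_sets(classify_de(det, fc_threshold=1.5, alpha=config.alpha))
            ora_frames = []
            for direction in ("up", "down"):
                ora = ora_gene_sets(sets[direction], background, collection)
                ora.insert(0, "direction", direction)
                ora_frames.append(ora)
            tio.write_table(pd.concat(ora_frames, ignore_index=True), out / "ora.tsv", header)

        if config.tf_ranks:
            stage = "tfrank"
            logger.info("stage tfrank: repeat-bearing TF rank test")
            tf_raw = tio.read_table(config.tf_ranks)
            if "significant" not in tf_raw.columns and "fdr" in tf_raw.columns:
                tf_raw["significant"] = tf_raw["fdr"] < config.tf_fdr_threshold
            tf_spec = DEFAULT_TF_SPEC if DEFAULT_TF_SPEC in catalog.sets else max(
                catalog.sets, key=lambda s: (s.unit == "CTG", s.min_units == 6)
            )
            flagged = flag_repeat_tfs(tf_raw, catalog, spec=tf_spec)
            tio.write_table(flagged, out / "tf_flags.tsv", header)
            ks = ks_rank_test(flagged, alternative=config.ks_alternative)
            (out / "tf_ks.json").write_text(json.dumps({
                "D": ks.d, "p": ks.p, "direction": ks.direction,
                "n_repeat": ks.n_repeat, "n_other": ks.n_other, "method": ks.method,
            }, indent=2) + "\n")
            if config.tf_edges:
                edges = tio.read_table(config.tf_edges)
                rep_tfs = frozenset(flagged.loc[flagged["repeat_bearing"] == True, "tf_id"])  # noqa: E712
                net = RegulatoryNetwork(edges=edges.drop_duplicates(), repeat_tfs=rep_tfs)
                from .de import classify_de as _cde, de_sets as _ds
                sets15 = _ds(_cde(det, fc_threshold=1.5, alpha=config.alpha))
                cov = network_coverage(net, sets15["both"], sets15["up"], sets15["down"])
                tio.write_table(cov["tf_out_degree"], out / "tf_coverage.tsv", header)
                (out / "tf_coverage.json").write_text(json.dumps({
                    "coverage_total": cov["coverage_total"],
                    "coverage_up": cov["coverage_up"],
                    "coverage_down": cov["coverage_down"],
                    "n_de": cov["n_de"], "n_covered": cov["n_covered"],
                }, indent=2) + "\n")

        if cm.phenotype is not None and cm.phenotype.notna().sum() >= 3:
            stage = "phenocorr"
            logger.info("stage phenocorr: expression-phenotype correlation")
            corr = gene_phenotype_correlation(nm)
            tio.write_table(corr.reset_index(), out / "phenotype_correlation.tsv", header)

        if config.plots:
            stage = "plots"
            from . import plots
            plots.enrichment_bars(grid, out / "enrichment_grid.png")
            plots.pca_scatter(emb, nm.condition, out / "pca.png")
            plots.heatmap(ordered, out / "heatmap.png")
    except PipelineError as exc:
        _write_error(out, stage, str(exc))
        raise
    except Exception as exc:  # pragma: no cover - defensive
        _write_error(out, stage, f"{type(exc).__name__}: {exc}")
        raise PipelineError(f"stage {stage} failed: {exc}", exit_code=1) from exc
    return out


def _write_error(out: Path, stage: str, message: str) -> None:
    try:
        (out / "error.json").write_text(
            json.dumps({"stage": stage, "error": message}, indent=2) + "\n"
        )
    except OSError:  # pragma: no cover
        pass
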