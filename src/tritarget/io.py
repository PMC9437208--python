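"""File formats: FASTA, TSV tables, GMT gene sets, catalog export.

All TSV outputs may carry leading ``#`` comment lines (package version,
config hash, seed); every reader here skips them. FASTA input is
gzip-transparent and headers are parsed up to the first whitespace as the
gene id.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .de import CASE, CONTROL, CountMatrix
from .repeat_scan import MotifSpec, RepeatCatalog

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_count_matrix",
    "read_de_table",
    "write_table",
    "read_table",
    "write_catalog",
    "read_catalog",
    "read_gmt",
    "write_gmt",
]


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(gene_id, sequence) records; id = header up to first whitespace."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for gene_id, seq in records:
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_table(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None,
                index: bool = False) -> None:
    """TSV with optional leading '# ' comment lines."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(cm: CountMatrix, path: str | Path, header_lines: list[str] | None = None) -> None:
    df = cm.counts.copy()
    df.index.name = "gene_id"
    write_table(df.reset_index(), path, header_lines)


def write_sample_sheet(cm: CountMatrix, path: str | Path,
                       header_lines: list[str] | None = None) -> None:
    sheet = pd.DataFrame({"sample_id": cm.samples, "condition": cm.condition.values})
    if cm.phenotype is not None:
        sheet["phenotype"] = cm.phenotype.values
    write_table(sheet, path, header_lines)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index(df.columns[0]).rename_axis("gene_id")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = read_table(path)
    required = {"sample_id", "condition"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}, got {list(sheet.columns)}")
    return sheet.set_index("sample_id")


def load_count_matrix(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = read_counts(counts_path)
    sheet = read_sample_sheet(samples_path)
    missing = set(counts.columns) - set(sheet.index)
    if missing:
        raise ValueError(f"samples without sheet entry: {sorted(missing)[:5]}")
    phenotype = sheet["phenotype"] if "phenotype" in sheet.columns else None
    return CountMatrix(
        counts=counts.astype(int),
        condition=sheet["condition"],
        phenotype=phenotype,
    )


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Externally produced DE table (gene_id, logFC, p, q [, t, status])."""
    det = read_table(path).set_index("gene_id")
    required = {"logFC", "p", "q"}
    if not required <= set(det.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    return det


def write_catalog(catalog: RepeatCatalog, path: str | Path,
                  header_lines: list[str] | None = None) -> None:
    """Long-format catalog TSV: one (unit, k, m, gene_id) row per member,
    plus a background section flagged in the ``in_background`` column."""
    rows = []
    for spec in catalog.specs:
        for g in sorted(catalog.genes(spec)):
            rows.append({"unit": spec.unit, "k": spec.min_units, "m": spec.max_mismatches,
                         "include_complement": spec.include_complement, "gene_id": g})
    member_df = pd.DataFrame(rows, columns=["unit", "k", "m", "include_complement", "gene_id"])
    bg_df = pd.DataFrame({"unit": "*", "k": 0, "m": 0, "include_complement": True,
                          "gene_id": sorted(catalog.background)})
    write_table(pd.concat([member_df, bg_df], ignore_index=True), path, header_lines)


def read_catalog(path: str | Path) -> RepeatCatalog:
    df = read_table(path)
    bg = frozenset(df.loc[df["unit"] == "*", "gene_id"])
    sets: dict[MotifSpec, frozenset[str]] = {}
    for (unit, k, m, inc), grp in df[df["unit"] != "*"].groupby(
        ["unit", "k", "m", "include_complement"]
    ):
        sets[MotifSpec(unit, int(k), int(m), bool(inc))] = frozenset(grp["gene_id"])
    return RepeatCatalog(sets=sets, background=bg)


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    """GMT: set name, description, then member genes, tab-separated."""
    collection: dict[str, frozenset[str]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            collection[parts[0]] = frozenset(g for g in parts[2:] if g)
    return collection


def write_gmt(collection: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
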