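"""Phase-free trinucleotide repeat scanning of transcript sequences.

Expanded CTG repeats are transcribed bidirectionally, so both CUG(n) and
CAG(n) repeat RNAs exist; repeat-derived siRNAs (~18 nt, i.e. six 3-nt
units) can silence transcripts that carry complementary endogenous runs.
This module finds genes whose representative transcript contains at least
``k`` consecutive units of a trinucleotide motif (or its reverse
complement), tolerating up to ``m`` mismatched nucleotides per 3k-window.

Matching is phase-free: a window qualifies if its Hamming distance to k
tandem copies of *any cyclic rotation* of either paired unit is within the
mismatch budget. Overlapping qualifying windows of the same matched unit
are merged into one maximal run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotifSpec",
    "RepeatHit",
    "RepeatCatalog",
    "reverse_complement",
    "rotation_family",
    "scan_sequence",
    "build_catalog",
    "catalog_summary",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset(b"ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _rotations(unit: str) -> tuple[str, ...]:
    return tuple(unit[i:] + unit[:i] for i in range(len(unit)))


def rotation_family(unit: str, include_complement: bool = True) -> frozenset[str]:
    """All cyclic rotations of ``unit`` (and of its reverse complement).

    Two motif specs with the same rotation family match exactly the same
    windows: e.g. CGG and GCG are rotations of each other, so phase-free
    scans for the CGG/CCG and GCG/CGC pairs yield identical gene sets.
    """
    fam = set(_rotations(unit))
    if include_complement:
        fam |= set(_rotations(reverse_complement(unit)))
    return frozenset(fam)


@dataclass(frozen=True, order=True)
class MotifSpec:
    """A repeat query: 3-mer unit, minimum unit count and mismatch budget.

    ``include_complement`` pairs the unit with its reverse complement
    (CTG <-> CAG), matching either member. ``max_mismatches`` is the
    per-window Hamming budget against k tandem unit copies.
    """

    unit: str
    min_units: int = 6
    max_mismatches: int = 0
    include_complement: bool = True

    def __post_init__(self) -> None:
        if len(self.unit) != 3 or any(c not in "ACGT" for c in self.unit):
            raise ValueError(f"motif unit must be a 3-letter DNA string, got {self.unit!r}")
        if self.min_units < 2:
            raise ValueError(f"min_units must be >= 2, got {self.min_units}")
        if not 0 <= self.max_mismatches <= 3 * self.min_units - 1:
            raise ValueError(
                f"max_mismatches must be in [0, {3 * self.min_units - 1}], got {self.max_mismatches}"
            )

    @property
    def units(self) -> tuple[str, ...]:
        """The matched unit(s), lexicographically sorted, deduplicated."""
        if not self.include_complement:
            return (self.unit,)
        rc = reverse_complement(self.unit)
        return tuple(sorted({self.unit, rc}))

    @property
    def family(self) -> frozenset[str]:
        """Rotation family defining the windows this spec can match."""
        return rotation_family(self.unit, self.include_complement)

    @property
    def window(self) -> int:
        return 3 * self.min_units

    def label(self) -> str:
        pair = f"{self.unit}/{reverse_complement(self.unit)}" if self.include_complement else self.unit
        return f"{pair} k>={self.min_units} m<={self.max_mismatches}"


@dataclass(frozen=True)
class RepeatHit:
    """One maximal repeat run: ``[start, start + 3*n_units)`` on the transcript."""

    gene_id: str
    start: int
    n_units: int
    matched_unit: str
    n_mismatches: int

    @property
    def end(self) -> int:
        return self.start + 3 * self.n_units


class ScanError(ValueError):
    """Raised on invalid sequence input or duplicate gene ids."""


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii", errors="replace"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ScanError(f"non-DNA character {seq[pos]!r} at position {pos} (only A/C/G/T/N allowed)")
    return arr


def _tiling_mismatch_cumsums(enc: np.ndarray, unit: str) -> list[np.ndarray]:
    """Per-phase cumulative mismatch counts of the sequence vs. an infinite
    tiling of ``unit``. N never matches any motif base."""
    n = enc.size
    reps = n // 3 + 2
    tiled = np.frombuffer((unit * reps).encode("ascii"), dtype=np.uint8)
    out = []
    for s in range(3):
        mism = (enc != tiled[s : s + n]).astype(np.int32)
        cs = np.empty(n + 1, dtype=np.int32)
        cs[0] = 0
        np.cumsum(mism, out=cs[1:])
        out.append(cs)
    return out


def _window_min_mismatches(cumsums: Sequence[np.ndarray], window: int) -> np.ndarray:
    """Minimum over the 3 rotations of the window mismatch count, per start.

    Aligning a window at start ``i`` against rotation ``r`` of the unit is
    equivalent to aligning it against the phase-``(r+i) mod 3`` tiling, so
    the rotation minimum equals the minimum over the three tilings.
    """
    n = cumsums[0].size - 1
    if n < window:
        return np.empty(0, dtype=np.int32)
    stacked = np.stack([cs[window:] - cs[: n - window + 1] for cs in cumsums])
    return stacked.min(axis=0)


def _merge_runs(starts: np.ndarray, mism: np.ndarray, window: int) -> list[tuple[int, int, int]]:
    """Merge overlapping qualifying windows into maximal runs.

    Returns (start, n_units, min_mismatches) triples. The reported window
    covers the whole units inside the union of the merged intervals.
    """
    runs: list[tuple[int, int, int]] = []
    if starts.size == 0:
        return runs
    cur_start = int(starts[0])
    cur_end = cur_start + window
    cur_m = int(mism[0])
    for s, m in zip(starts[1:], mism[1:]):
        s = int(s)
        if s < cur_end:  # overlap -> same maximal run
            cur_end = s + window
            cur_m = min(cur_m, int(m))
        else:
            runs.append((cur_start, (cur_end - cur_start) // 3, cur_m))
            cur_start, cur_end, cur_m = s, s + window, int(m)
    runs.append((cur_start, (cur_end - cur_start) // 3, cur_m))
    return runs


def scan_sequence(seq: str, spec: MotifSpec, gene_id: str = "") -> list[RepeatHit]:
    """All maximal repeat runs of ``spec`` in ``seq``, sorted by start.

    A 3k-window qualifies if its Hamming distance to k tandem copies of any
    cyclic rotation of either paired unit is <= the mismatch budget;
    overlapping qualifying windows of the same matched unit merge into one
    maximal run reporting the units covered and the minimal mismatch count.
    """
    enc = _encode(seq)
    window = spec.window
    hits: list[RepeatHit] = []
    seen: dict[tuple[int, int], int] = {}
    for unit in spec.units:  # lexicographic order; ties keep the smaller unit
        cumsums = _tiling_mismatch_cumsums(enc, unit)
        wm = _window_min_mismatches(cumsums, window)
        qual = np.flatnonzero(wm <= spec.max_mismatches)
        for start, n_units, m in _merge_runs(qual, wm[qual], window):
            key = (start, n_units)
            if key in seen:  # palindromic tie: keep lexicographically smaller unit
                continue
            seen[key] = len(hits)
            hits.append(RepeatHit(gene_id, start, n_units, unit, m))
    hits.sort(key=lambda h: (h.start, h.matched_unit))
    return hits


@dataclass
class RepeatCatalog:
    """Genes matching each motif spec, plus the scanned background universe."""

    sets: dict[MotifSpec, frozenset[str]] = field(default_factory=dict)
    background: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for spec, genes in self.sets.items():
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"catalog genes outside background for {spec.label()}: {sorted(stray)[:5]}"
                )

    def genes(self, spec: MotifSpec) -> frozenset[str]:
        return self.sets[spec]

    @property
    def specs(self) -> list[MotifSpec]:
        return sorted(self.sets)


def build_catalog(
    transcripts: Iterable[tuple[str, str]], specs: Sequence[MotifSpec]
) -> RepeatCatalog:
    """Scan one representative transcript per gene against every spec.

    Duplicate gene ids are rejected: deduplication to one transcript per
    gene is the caller's responsibility.
    """
    specs = list(specs)
    members: dict[MotifSpec, set[str]] = {spec: set() for spec in specs}
    background: set[str] = set()
    # group specs per unit so tiling cumsums are computed once per unit
    unit_groups: dict[str, list[MotifSpec]] = {}
    for spec in specs:
        for unit in spec.units:
            unit_groups.setdefault(unit, []).append(spec)
    for gene_id, seq in transcripts:
        if gene_id in background:
            raise ScanError(f"duplicate gene_id {gene_id!r}; provide one transcript per gene")
        background.add(gene_id)
        try:
            enc = _encode(seq)
        except ScanError as exc:
            raise ScanError(f"{gene_id}: {exc}") from None
        for unit, unit_specs in unit_groups.items():
            cumsums = _tiling_mismatch_cumsums(enc, unit)
            by_window: dict[int, np.ndarray] = {}
            for spec in unit_specs:
                if gene_id in members[spec]:
                    continue
                if spec.window not in by_window:
                    by_window[spec.window] = _window_min_mismatches(cumsums, spec.window)
                wm = by_window[spec.window]
                if wm.size and int(wm.min()) <= spec.max_mismatches:
                    members[spec].add(gene_id)
    return RepeatCatalog(
        sets={spec: frozenset(genes) for spec, genes in members.items()},
        background=frozenset(background),
    )


def catalog_summary(catalog: RepeatCatalog) -> pd.DataFrame:
    """Per-spec gene counts and prevalence, ordered by (unit, k, m)."""
    if not catalog.background:
        raise ValueError("catalog has an empty background; nothing was scanned")
    n_bg = len(catalog.background)
    rows = []
    for spec in sorted(catalog.sets, key=lambda s: (s.unit, s.min_units, s.max_mismatches)):
        n = len(catalog.sets[spec])
        rows.append(
            {
                "unit": spec.unit,
                "include_complement": spec.include_complement,
                "k": spec.min_units,
                "m": spec.max_mismatches,
                "n_genes": n,
                "prevalence": n / n_bg,
            }
        )
    return pd.DataFrame(rows)


def hits_table(hits: Iterable[RepeatHit]) -> pd.DataFrame:
    """BED-like long table of hits (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            {
                "gene_id": h.gene_id,
                "start": h.start,
                "end": h.end,
                "matched_unit": h.matched_unit,
                "n_units": h.n_units,
                "n_mismatches": h.n_mismatches,
            }
            for h in hits
        ],
        columns=["gene_id", "start", "end", "matched_unit", "n_units", "n_mismatches"],
    )


def scan_transcripts(
    transcripts: Iterable[tuple[str, str]], specs: Sequence[MotifSpec]
) -> dict[MotifSpec, list[RepeatHit]]:
    """Per-spec hit lists across a transcript set (for BED-like export)."""
    out: dict[MotifSpec, list[RepeatHit]] = {spec: [] for spec in specs}
    seen: set[str] = set()
    for gene_id, seq in transcripts:
        if gene_id in seen:
            raise ScanError(f"duplicate gene_id {gene_id!r}; provide one transcript per gene")
        seen.add(gene_id)
        for spec in specs:
            out[spec].extend(scan_sequence(seq, spec, gene_id=gene_id))
    return out
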