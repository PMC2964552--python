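"""Reading and filtering per-locus multiple sequence alignments.

A locus is a FASTA alignment of resequenced haplotypes from two populations
(wild green foxtail and cultivated foxtail millet, plus an optional outgroup
record), a sample-to-population map, and a BED-like annotation of coding
intervals.  Coordinates in annotation files are 0-based, half-open.

Filtering follows the resequencing-survey convention: samples with excessive
missing data are dropped, then every column containing a gap or an ambiguous
base in any retained sample is removed, so downstream statistics see a
rectangular {A,C,G,T} matrix.  Silent-site totals combine noncoding columns
with fractional synonymous-site counts (equal-weight Nei-Gojobori counting)
over the coding codons that survive filtering intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

VALID_BASES = frozenset(b"ACGT")
POPULATIONS = ("wild", "cultivated", "outgroup")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


@dataclass
class CodingInterval:
    """A coding stretch on the alignment's own strand.

    ``frame`` is the offset (0-2) of the first complete codon relative to
    ``start``; columns before that offset are coding but belong to a codon
    that starts outside the interval and contribute no synonymous sites.
    """

    start: int
    end: int
    frame: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")


@dataclass
class LocusAlignment:
    """An aligned sample of haplotypes for one locus."""

    locus_id: str
    sample_ids: list[str]
    population_of: dict[str, str]
    matrix: np.ndarray  # (n_samples, n_columns), dtype 'S1', uppercase
    coding: list[CodingInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise ValueError("alignment matrix must be 2-D")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("sample_ids / matrix row mismatch")
        missing = [s for s in self.sample_ids if s not in self.population_of]
        if missing:
            raise ValueError(f"samples without population label: {missing}")
        for iv in self.coding:
            if iv.end > self.n_columns:
                raise ValueError(
                    f"{self.locus_id}: coding interval [{iv.start}, {iv.end}) "
                    f"exceeds alignment span {self.n_columns}"
                )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def populations(self) -> np.ndarray:
        return np.array([self.population_of[s] for s in self.sample_ids])


@dataclass
class FilteredAlignment:
    """A gap- and N-free view of a :class:`LocusAlignment`.

    ``L_total`` is the surviving alignment length in bp, ``L_silent`` the
    (possibly fractional) silent length: noncoding columns plus synonymous
    site fractions of intact coding codons.
    """

    parent: LocusAlignment
    kept_columns: np.ndarray
    sample_ids: list[str]
    matrix: np.ndarray
    L_total: int
    L_silent: float

    @property
    def locus_id(self) -> str:
        return self.parent.locus_id

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def population_of(self, sample: str) -> str:
        return self.parent.population_of[sample]

    def populations(self) -> np.ndarray:
        return np.array([self.parent.population_of[s] for s in self.sample_ids])

    def rows(self, pop: str | None = None) -> np.ndarray:
        """Return the character matrix, optionally restricted to one population."""
        if pop is None:
            return self.matrix
        mask = self.populations() == pop
        if not mask.any():
            raise ValueError(f"population {pop!r} absent from {self.locus_id}")
        return self.matrix[mask]


def read_popmap(path: str | Path) -> dict[str, str]:
    """Read a two-column sample_id / population TSV (comments '#', CRLF ok)."""
    popmap: dict[str, str] = {}
    with open(path, newline=None) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            sample, pop = parts[0], parts[1]
            if pop not in POPULATIONS:
                raise ValueError(f"unknown population {pop!r} for sample {sample!r}")
            popmap[sample] = pop
    if not popmap:
        raise ValueError(f"empty popmap: {path}")
    return popmap


def read_annotation(path: str | Path) -> dict[str, list[CodingInterval]]:
    """Read a BED-like TSV of coding intervals, keyed by locus id.

    Columns: locus, start, end, class, frame.  Intervals are 0-based
    half-open on the alignment's own strand.  Rows with class 'noncoding'
    are tolerated and ignored (noncoding is the default for unannotated
    columns).  Overlapping coding intervals are an error.
    """
    by_locus: dict[str, list[CodingInterval]] = {}
    with open(path, newline=None) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed annotation line: {line!r}")
            locus, start, end, cls = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if cls == "noncoding":
                continue
            if cls != "coding":
                raise ValueError(f"unknown annotation class {cls!r}")
            frame = int(parts[4]) if len(parts) > 4 else 0
            by_locus.setdefault(locus, []).append(CodingInterval(start, end, frame))
    for locus, ivs in by_locus.items():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError(f"{locus}: overlapping coding intervals")
    return by_locus


def read_alignment(
    fasta_path: str | Path,
    annotation_path: str | Path | None = None,
    popmap_path: str | Path | None = None,
    *,
    popmap: dict[str, str] | None = None,
    locus_id: str | None = None,
) -> LocusAlignment:
    """Read one locus FASTA into a :class:`LocusAlignment`.

    All records must have equal length ("ragged alignment" otherwise) and
    every record id must appear in the popmap.  The locus id defaults to the
    FASTA file stem; the annotation file may cover several loci.
    """
    fasta_path = Path(fasta_path)
    locus_id = locus_id or fasta_path.stem
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {fasta_path}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{locus_id}: ragged alignment (lengths {sorted(lengths)})")
    if popmap is None:
        if popmap_path is None:
            raise ValueError("either popmap or popmap_path is required")
        popmap = read_popmap(popmap_path)
    unknown = [r.id for r in records if r.id not in popmap]
    if unknown:
        raise ValueError(f"{locus_id}: samples absent from popmap: {unknown}")
    matrix = np.array(
        [np.frombuffer(str(r.seq).upper().encode(), dtype="S1") for r in records]
    )
    coding: list[CodingInterval] = []
    if annotation_path is not None:
        coding = read_annotation(annotation_path).get(locus_id, [])
    return LocusAlignment(
        locus_id=locus_id,
        sample_ids=[r.id for r in records],
        population_of={r.id: popmap[r.id] for r in records},
        matrix=matrix,
        coding=coding,
    )


def filter_sites(
    aln: LocusAlignment, *, max_missing_frac: float = 0.2
) -> FilteredAlignment:
    """Drop high-missingness samples, then all columns with a gap or N.

    A sample is dropped when more than ``max_missing_frac`` of its columns
    are not in {A,C,G,T}; remaining offending columns are removed column-wise.
    Idempotent: filtering a filtered alignment changes nothing.
    """
    if aln.n_samples == 0 or aln.n_columns == 0:
        raise ValueError(f"{aln.locus_id}: empty alignment")
    ok = np.isin(aln.matrix, [b"A", b"C", b"G", b"T"])
    keep_samples = ok.mean(axis=1) >= 1.0 - max_missing_frac
    if not keep_samples.any():
        raise ValueError(f"{aln.locus_id}: all samples exceed missing-data threshold")
    kept_cols = np.flatnonzero(ok[keep_samples].all(axis=0))
    if kept_cols.size == 0:
        raise ValueError(f"{aln.locus_id}: no analyzable sites")
    sample_ids = [s for s, k in zip(aln.sample_ids, keep_samples) if k]
    matrix = aln.matrix[np.ix_(keep_samples, kept_cols)]
    fa = FilteredAlignment(
        parent=aln,
        kept_columns=kept_cols,
        sample_ids=sample_ids,
        matrix=matrix,
        L_total=int(kept_cols.size),
        L_silent=np.nan,
    )
    fa.L_silent = count_silent_sites(fa)
    return fa


def synonymous_site_count(codon: bytes) -> float:
    """Equal-weight synonymous site count of one codon.

    Each position contributes (number of synonymous one-step changes)/3;
    changes to stop codons count as nonsynonymous, and stop codons
    themselves contribute 0 (they encode no amino acid to preserve).
    """
    return _SYN_SITES[codon]


def _syn_sites_table() -> dict[bytes, float]:
    bases = b"ACGT"
    table: dict[bytes, float] = {}
    fwd = _STANDARD_TABLE.forward_table
    for c1 in bases:
        for c2 in bases:
            for c3 in bases:
                codon = bytes([c1, c2, c3])
                aa = fwd.get(codon.decode())
                if aa is None:  # stop codon
                    table[codon] = 0.0
                    continue
                syn = 0
                for pos in range(3):
                    for b in bases:
                        if b == codon[pos]:
                            continue
                        mutant = codon[:pos] + bytes([b]) + codon[pos + 1 :]
                        if fwd.get(mutant.decode()) == aa:
                            syn += 1
                table[codon] = syn / 3.0
    return table


_SYN_SITES = _syn_sites_table()


def count_silent_sites(aln: FilteredAlignment) -> float:
    """Silent length of a filtered alignment, in (fractional) bp.

    Noncoding surviving columns count 1 each.  A coding codon whose three
    columns all survive filtering contributes its synonymous site count,
    averaged over the retained sequences (so a polymorphic codon can give a
    fractional, sample-dependent value).  Coding columns whose codon was
    broken by filtering, or that precede the first in-frame codon,
    contribute 0.
    """
    parent = aln.parent
    kept = aln.kept_columns
    col_of = {int(c): i for i, c in enumerate(kept)}
    coding_cols = np.zeros(parent.n_columns, dtype=bool)
    silent = 0.0
    for iv in parent.coding:
        span = iv.end - iv.start - iv.frame
        if span % 3 != 0:
            raise ValueError(
                f"{parent.locus_id}: coding span [{iv.start}, {iv.end}) frame "
                f"{iv.frame} not divisible by 3"
            )
        coding_cols[iv.start : iv.end] = True
        for c0 in range(iv.start + iv.frame, iv.end, 3):
            cols = (c0, c0 + 1, c0 + 2)
            if not all(c in col_of
                       for c in cols):
                continue
            idx = [col_of[c] for c in cols]
            codons = aln.matrix[:, idx]
            vals = [synonymous_site_count(bytes(row)) for row in codons]
            silent += float(np.mean(vals))
    noncoding = int((~coding_cols[kept]).sum())
    return noncoding + silent
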