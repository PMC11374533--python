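"""Shared domain types, coordinate conventions, and file I/O.

All internal coordinates are 0-based half-open. BED and bedGraph are emitted
natively in that convention; GFF3 export converts to 1-based inclusive at the
boundary. Fragment midpoints are ``floor((start + end) / 2)`` throughout — a
deterministic integer convention that every downstream stage (window
assignment, phasing, feature overlap) relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Malformed input file (bad FASTA/BED/bedGraph content)."""


class BoundsError(ValueError):
    """An interval violates chromosome bounds or start/end ordering."""


_VALID_BASES = frozenset("ACGTN")
_STRANDS = frozenset({"+", "-", "."})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise BoundsError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeSequence:
    """A named chromosome sequence over {A, C, G, T, N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains illegal characters: "
                f"{sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


class Genome(Mapping[str, GenomeSequence]):
    """An ordered collection of uniquely named chromosomes."""

    def __init__(self, sequences: Iterable[GenomeSequence]):
        self._seqs: dict[str, GenomeSequence] = {}
        for s in sequences:
            if s.name in self._seqs:
                raise FormatError(f"duplicate chromosome name {s.name!r}")
            self._seqs[s.name] = s

    def __getitem__(self, name: str) -> GenomeSequence:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    @property
    def names(self) -> list[str]:
        return list(self._seqs)

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self._seqs.values())

    def lengths(self) -> dict[str, int]:
        return {n: s.length for n, s in self._seqs.items()}


class FragmentSet:
    """Sequenced ChIP or input fragments as genomic intervals.

    Storage is columnar (per-chromosome start/end arrays) so that window
    assignment and midpoint arithmetic over 1e5+ fragments stay vectorised;
    the ``fragments`` property exposes the interval view.
    """

    def __init__(self, label: str, by_chrom: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.label = label
        self.by_chrom = {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in by_chrom.items()
        }
        for c, (s, e) in self.by_chrom.items():
            if len(s) != len(e):
                raise BoundsError(f"start/end length mismatch on {c}")
            if len(s) and (np.any(s < 0) or np.any(s >= e)):
                raise BoundsError(f"fragments on {c} violate 0 <= start < end")

    @classmethod
    def from_intervals(cls, label: str, intervals: Iterable[GenomicInterval]) -> "FragmentSet":
        acc: dict[str, tuple[list[int], list[int]]] = {}
        for iv in intervals:
            s, e = acc.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return cls(label, {c: (np.array(s), np.array(e)) for c, (s, e) in acc.items()})

    @property
    def total_count(self) -> int:
        return sum(len(s) for s, _ in self.by_chrom.values())

    @property
    def fragments(self) -> Iterator[GenomicInterval]:
        for c, (s, e) in self.by_chrom.items():
            for a, b in zip(s.tolist(), e.tolist()):
                yield GenomicInterval(c, a, b)

    def midpoints(self, chrom: str) -> np.ndarray:
        s, e = self.by_chrom.get(chrom, (np.empty(0, np.int64),) * 2)
        return (s + e) // 2

    def validate_against(self, genome: Genome) -> None:
        unknown = [c for c in self.by_chrom if c not in genome]
        if unknown:
            raise BoundsError(f"fragments on unknown chromosomes: {unknown}")
        for c, (s, e) in self.by_chrom.items():
            if len(e) and int(e.max()) > genome[c].length:
                raise BoundsError(
                    f"fragment end {int(e.max())} exceeds {c} length {genome[c].length}"
                )

    def counts_by_chrom(self) -> dict[str, int]:
        return {c: len(s) for c, (s, _) in self.by_chrom.items()}


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    seqs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            seqs.append(GenomeSequence(rec.id, str(rec.seq)))
        except FormatError as err:
            raise FormatError(f"{path}: record {rec.id!r}: {err}") from err
    return Genome(seqs)


def write_fasta(genome: Genome | Iterable[GenomeSequence], path: str | Path, width: int = 60) -> None:
    seqs = genome.values() if isinstance(genome, Genome) else genome
    records = [SeqRecord(Seq(s.sequence), id=s.name, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED fragments
# ---------------------------------------------------------------------------

def read_fragments_bed(path: str | Path, genome: Genome, label: str = "input") -> FragmentSet:
    """Read a BED3+ file of fragments, validated against the genome."""
    acc: dict[str, tuple[list[int], list[int]]] = {}
    unknown: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as err:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from err
            if start >= end or start < 0:
                raise FormatError(f"{path}:{lineno}: need 0 <= start < end")
            if chrom not in genome:
                unknown.add(chrom)
                continue
            s, e = acc.setdefault(chrom, ([], []))
            s.append(start)
            e.append(end)
    if unknown:
        raise FormatError(f"{path}: unknown chromosomes: {sorted(unknown)}")
    fs = FragmentSet(label, {c: (np.array(s), np.array(e)) for c, (s, e) in acc.items()})
    fs.validate_against(genome)
    return fs


def write_fragments_bed(fragments: FragmentSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in sorted(fragments.by_chrom):
            s, e = fragments.by_chrom[c]
            for a, b in zip(s.tolist(), e.tolist()):
                fh.write(f"{c}\t{a}\t{b}\n")


def read_fragments_bam(path: str | Path, genome: Genome, label: str = "input",
                       min_mapq: int = 0) -> FragmentSet:
    """Optional convenience: extract fragments from a coordinate-sorted
    SAM/BAM.  Proper pairs contribute their template span; single-end reads
    their alignment span.  Reads below ``min_mapq`` are dropped.
    """
    import pysam  # local import: optional dependency path

    acc: dict[str, tuple[list[int], list[int]]] = {}
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if read.is_paired:
                if not read.is_proper_pair or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start, end = read.reference_start, read.reference_end
            chrom = read.reference_name
            s, e = acc.setdefault(chrom, ([], []))
            s.append(start)
            e.append(end)
    fs = FragmentSet(label, {c: (np.array(s), np.array(e)) for c, (s, e) in acc.items()})
    fs.validate_against(genome)
    return fs


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: "list[tuple[str, int, int, float]]", path: str | Path) -> None:
    """Write (chrom, start, end, value) windows as bedGraph.

    Windows must tile each chromosome without overlap; values are printed with
    six significant digits.
    """
    last_end: dict[str, int] = {}
    with open(path, "w") as fh:
        for chrom, start, end, value in track:
            if start < last_end.get(chrom, 0):
                raise BoundsError(
                    f"overlapping windows on {chrom} at {start} (previous end "
                    f"{last_end[chrom]})"
                )
            last_end[chrom] = end
            fh.write(f"{chrom}\t{start}\t{end}\t{value:#.6g}\n")


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            rows.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    return rows


# ---------------------------------------------------------------------------
# JSON / GFF3 helpers
# ---------------------------------------------------------------------------

def write_json(obj: object, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2, separators=(",", ": "))
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)


def write_gff3(features: Iterable[tuple[GenomicInterval, str, str, dict]], path: str | Path,
               source: str = "centroscape") -> None:
    """Write features as GFF3 (converting to 1-based inclusive coordinates).

    Each feature is ``(interval, type, feature_id, extra_attributes)``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, ftype, fid, attrs in features:
            attr = ";".join([f"ID={fid}"] + [f"{k}={v}" for k, v in sorted(attrs.items())])
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attr}\n"
            )
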