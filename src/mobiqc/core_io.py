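"""Sequence and interval primitives shared by every pipeline stage.

All coordinates are 0-based half-open internally. BED is read and written
as-is; GTF (and SAM, handled in :mod:`mobiqc.micromap`) use 1-based
coordinates and are converted at the boundary. Genome sequences are
restricted to the alphabet ``{A, C, G, T, N}``; lowercase input is upcased
on read. N is legal in genomes (masking) but the read simulator never
emits reads containing N.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution, N maps to N."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid nucleotide(s) {sorted(bad)} in sequence")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"malformed interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        """Half-open overlap test: intersection length >= 1 nt."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class Genome:
    """Ordered collection of named chromosome sequences.

    Names must be unique, sequences non-empty and drawn from
    ``{A, C, G, T, N}``.
    """

    def __init__(self, records: Sequence[tuple[str, str]]):
        self.records: list[tuple[str, str]] = []
        self._by_name: dict[str, str] = {}
        for name, seq in records:
            if name in self._by_name:
                raise ValueError(f"duplicate record name {name!r}")
            if not seq:
                raise ValueError(f"empty sequence for record {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"non-IUPAC character(s) {sorted(bad)} in record {name!r}"
                )
            self.records.append((name, seq))
            self._by_name[name] = seq

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.records]

    def seq(self, name: str) -> str:
        return self._by_name[name]

    def length(self, name: str) -> int:
        return len(self._by_name[name])

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self.records == other.records


class ElementLibrary(Genome):
    """A set of element (transposon family or IGE) consensus sequences."""

    @property
    def total_nt(self) -> int:
        return self.total_length


def read_fasta(path, library: bool = False):
    """Read a FASTA file into a :class:`Genome` or :class:`ElementLibrary`.

    Line wrapping is removed, lowercase is upcased; duplicate names, empty
    sequences, and characters outside {A,C,G,T,N} are hard errors.
    """
    records = []
    with open(path) as fh:
        for name, seq in SimpleFastaParser(fh):
            records.append((name.split()[0] if name else name, seq.upper()))
    cls = ElementLibrary if library else Genome
    return cls(records)


def write_fasta(genome: Genome, path, wrap: int = 70) -> None:
    """Write records in order at a fixed wrap width (round-trip stable)."""
    with open(path, "w") as fh:
        for name, seq in genome.records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def flank_intervals(
    intervals: Iterable[Interval], pad: int, genome: Genome
) -> list[Interval]:
    """Extend each interval by ``pad`` nt on both sides, clipped to the
    chromosome bounds. Unknown chromosome is a hard error."""
    out = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        clen = genome.length(iv.chrom)
        out.append(
            replace(iv, start=max(0, iv.start - pad), end=min(clen, iv.end + pad))
        )
    return out


def subtract_overlapping(
    a: Sequence[Interval], b: Sequence[Interval]
) -> list[Interval]:
    """Members of ``a`` with zero overlap against every member of ``b``.

    Overlap is the half-open test (touching intervals do not overlap);
    input order of ``a`` is preserved.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in b:
        if iv.length > 0:
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None or not tree.overlaps(iv.start, iv.end):
            kept.append(iv)
    return kept


def read_bed(path) -> list[Interval]:
    """Read BED (3-6 columns) into intervals; coordinates taken verbatim."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(Interval(f[0], int(f[1]), int(f[2]), name, strand))
    return out


def write_bed(intervals: Iterable[Interval], path, extra=None) -> None:
    """Write BED6; ``extra`` maps an interval index to extra columns."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end), iv.name or ".", "0", iv.strand]
            if extra is not None:
                cols.extend(str(x) for x in extra[i])
            fh.write("\t".join(cols) + "\n")


def read_gtf(path, feature: str | None = None) -> list[Interval]:
    """Minimal GTF reader: seqname/feature/start/end/strand plus a
    ``gene_id`` attribute used as the interval name. 1-based closed
    coordinates are converted to 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if feature is not None and f[2] != feature:
                continue
            name = ""
            for part in f[8].split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    name = part.split(None, 1)[1].strip('"')
                    break
            out.append(Interval(f[0], int(f[3]) - 1, int(f[4]), name, f[6]))
    return out


def write_gtf(intervals: Iterable[Interval], path, source="mobiqc", feature="exon"):
    with open(path, "w") as fh:
        for iv in intervals:
            attrs = f'gene_id "{iv.name}"; transcript_id "{iv.name}";'
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        source,
                        feature,
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        iv.strand if iv.strand != "." else "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
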