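"""Deterministic exact-match paired-end mapper for error-free reads.

A sorted k-mer index over the forward strand drives seeding; a hit is
accepted only on full-length exact extension, so mapping is exact and
complete for reads simulated without sequencing error. Reads that fail
full-length placement (breakpoint- or junction-spanning mates) fall back
to the longest exact prefix/suffix anchor, recorded as a soft-clipped
placement — mirroring how such reads surface in real aligner output.
Ambiguous reads are never placed arbitrarily; they are flagged and
excluded from insertion evidence downstream.

Real alignments can be ingested instead via :func:`read_sam`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .core_io import ElementLibrary, Genome, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class KmerIndex:
    """Exact k-mer -> forward-strand positions map over a genome.

    Positions whose k-mer window contains N (or any non-ACGT base) are
    excluded. ``k`` must be in [11, 31] and no longer than the shortest
    chromosome.
    """

    def __init__(self, genome: Genome, k: int = 21):
        if not 11 <= k <= 31:
            raise ValueError("k must be between 11 and 31")
        shortest = min(len(s) for _, s in genome.records)
        if k > shortest:
            raise ValueError("k exceeds the shortest chromosome")
        self.genome = genome
        self.k = k
        self._names = genome.names
        self._seqs = {n: s for n, s in genome.records}
        lengths = [len(s) for _, s in genome.records]
        self._offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)

        codes_parts, pos_parts = [], []
        for ci, (name, seq) in enumerate(genome.records):
            arr = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            n = len(arr) - k + 1
            if n <= 0:
                continue
            km = np.zeros(n, dtype=np.uint64)
            bad = np.zeros(n, dtype=bool)
            for j in range(k):
                window = arr[j : j + n]
                km = (km << np.uint64(2)) | window.astype(np.uint64)
                bad |= window > 3
            keep = ~bad
            codes_parts.append(km[keep])
            pos_parts.append(np.nonzero(keep)[0].astype(np.int64) + self._offsets[ci])
        codes = np.concatenate(codes_parts)
        pos = np.concatenate(pos_parts)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]

    def encode(self, s: str) -> int | None:
        v = 0
        for ch in s:
            c = _CODE[ord(ch)]
            if c > 3:
                return None
            v = (v << 2) | int(c)
        return v

    def lookup(self, s: str) -> np.ndarray:
        """Global positions of an exact k-mer (forward strand)."""
        if len(s) != self.k:
            raise ValueError("query length must equal k")
        code = self.encode(s)
        if code is None:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._codes, np.uint64(code), "left")
        hi = np.searchsorted(self._codes, np.uint64(code), "right")
        return self._pos[lo:hi]

    def locate(self, gpos: int) -> tuple[str, int]:
        ci = int(np.searchsorted(self._offsets, gpos, "right")) - 1
        return self._names[ci], int(gpos - self._offsets[ci])


@dataclass
class MatePlacement:
    status: str  # unique | ambiguous | unmapped
    chrom: str | None = None
    pos: int | None = None  # 0-based leftmost aligned position
    strand: str | None = None
    aln_len: int = 0
    clip_left: int = 0  # clipped bases on the low-coordinate genomic side
    clip_right: int = 0

    @property
    def unique(self) -> bool:
        return self.status == "unique"

    @property
    def clipped(self) -> bool:
        return self.clip_left + self.clip_right > 0

    @property
    def end(self) -> int:
        return self.pos + self.aln_len


@dataclass
class AlignedPair:
    name: str
    seq1: str
    seq2: str
    mate1: MatePlacement = field(default_factory=lambda: MatePlacement("unmapped"))
    mate2: MatePlacement = field(default_factory=lambda: MatePlacement("unmapped"))

    @property
    def insert_size(self) -> int | None:
        """Outer distance when both mates are uniquely placed on one
        chromosome; None otherwise."""
        m1, m2 = self.mate1, self.mate2
        if m1.unique and m2.unique and m1.chrom == m2.chrom:
            return max(m1.end, m2.end) - min(m1.pos, m2.pos)
        return None

    def concordant(self, lo: int, hi: int) -> bool:
        """Proper FR pair with full-length placements and an insert size
        inside [lo, hi]."""
        m1, m2 = self.mate1, self.mate2
        if not (m1.unique and m2.unique) or m1.clipped or m2.clipped:
            return False
        if m1.chrom != m2.chrom or m1.strand == m2.strand:
            return False
        left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
        if left.strand != "+":
            return False
        ins = self.insert_size
        return ins is not None and lo <= ins <= hi


class Mapper:
    """Seed-and-verify exact mapper over a genome."""

    def __init__(self, genome: Genome, k: int = 21):
        self.index = KmerIndex(genome, k)
        self.k = k

    def _full_hits(self, seq: str, cap: int = 2) -> list[tuple[str, int, str]]:
        L = len(seq)
        k = self.k
        if L < k:
            return []
        hits = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for gp in self.index.lookup(s[:k]):
                chrom, p = self.index.locate(int(gp))
                ref = self.index._seqs[chrom]
                if ref[p : p + L] == s:
                    hits.append((chrom, p, strand))
                    if len(hits) >= cap:
                        return hits
        return hits

    def _best_anchor(self, seq: str) -> MatePlacement | None:
        """Longest exact prefix/suffix anchor >= k, as a clipped placement.

        A tie between distinct maximal placements yields an ambiguous
        status (no arbitrary choice)."""
        L = len(seq)
        k = self.k
        if L < k:
            return None
        candidates = []  # (aln_len, chrom, gstart, strand, genomic clip side)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for gp in self.index.lookup(s[:k]):
                chrom, p = self.index.locate(int(gp))
                ref = self.index._seqs[chrom]
                e = k
                while e < L and p + e < len(ref) and ref[p + e] == s[e]:
                    e += 1
                candidates.append((e, chrom, p, strand, "right"))
            for gp in self.index.lookup(s[-k:]):
                chrom, p = self.index.locate(int(gp))
                ref = self.index._seqs[chrom]
                b = 0
                while b < L - k and p - 1 - b >= 0 and ref[p - 1 - b] == s[L - k - 1 - b]:
                    b += 1
                candidates.append((k + b, chrom, p - b, strand, "left"))
        if not candidates:
            return None
        best_len = max(c[0] for c in candidates)
        top = {(c[1], c[2], c[3], c[4]) for c in candidates if c[0] == best_len}
        placements = {(c, p) for c, p, _, _ in top}
        if len(placements) > 1:
            return MatePlacement("ambiguous")
        chrom, p, strand, side = sorted(top)[0]
        clip = len(seq) - best_len
        return MatePlacement(
            "unique",
            chrom,
            p,
            strand,
            aln_len=best_len,
            clip_left=clip if side == "left" else 0,
            clip_right=clip if side == "right" else 0,
        )

    def place_read(self, seq: str) -> MatePlacement:
        hits = self._full_hits(seq, cap=2)
        if len(hits) == 1:
            chrom, p, strand = hits[0]
            return MatePlacement("unique", chrom, p, strand, aln_len=len(seq))
        if len(hits) >= 2:
            return MatePlacement("ambiguous")
        anchor = self._best_anchor(seq)
        return anchor if anchor is not None else MatePlacement("unmapped")

    def map_pair(self, name: str, seq1: str, seq2: str) -> AlignedPair:
        return AlignedPair(name, seq1, seq2, self.place_read(seq1), self.place_read(seq2))

    def map_pairs(self, pairs) -> list[AlignedPair]:
        return [self.map_pair(n, s1, s2) for n, s1, s2 in pairs]


class ElementClassifier:
    """Assigns a read to the unique element family containing it exactly.

    A read present in more than one family is reported as unclassified
    with an ambiguity flag; a read absent from the library is simply
    unclassified.
    """

    def __init__(self, elements: ElementLibrary, k: int = 21):
        self.index = KmerIndex(elements, k)
        self.k = k

    def classify(self, seq: str) -> tuple[str | None, bool]:
        L = len(seq)
        k = self.k
        if L < k:
            return None, False
        families: set[str] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for gp in self.index.lookup(s[:k]):
                chrom, p = self.index.locate(int(gp))
                ref = self.index._seqs[chrom]
                if ref[p : p + L] == s:
                    families.add(chrom)
                    if len(families) > 1:
                        return None, True
        if len(families) == 1:
            return families.pop(), False
        return None, False


# --- SAM interchange (minimal dialect: @SQ header, M/S CIGAR only) ---


def write_sam(pairs, genome: Genome, path) -> None:
    """Write aligned pairs as SAM. Ambiguous mates are stored unmapped
    with a ``ZS:A:A`` tag so the round trip preserves their status."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(s)} for n, s in genome.records],
    }
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for pair in pairs:
            mates = [(pair.mate1, pair.seq1, True), (pair.mate2, pair.seq2, False)]
            for (mate, seq, first), (other, _, _) in zip(
                mates, [mates[1], mates[0]]
            ):
                a = pysam.AlignedSegment(out.header)
                a.query_name = pair.name
                flag = 0x1 | (0x40 if first else 0x80)
                if mate.unique:
                    if mate.strand == "-":
                        flag |= 0x10
                else:
                    flag |= 0x4
                if other.unique:
                    if other.strand == "-":
                        flag |= 0x20
                else:
                    flag |= 0x8
                a.flag = flag
                if mate.unique:
                    a.reference_name = mate.chrom
                    a.reference_start = mate.pos
                    a.mapping_quality = 60
                    cigar = []
                    if mate.clip_left:
                        cigar.append((4, mate.clip_left))
                    cigar.append((0, mate.aln_len))
                    if mate.clip_right:
                        cigar.append((4, mate.clip_right))
                    a.cigartuples = cigar
                    a.query_sequence = revcomp(seq) if mate.strand == "-" else seq
                else:
                    a.query_sequence = seq
                    if mate.status == "ambiguous":
                        a.set_tag("ZS", "A")
                if other.unique:
                    a.next_reference_name = other.chrom
                    a.next_reference_start = other.pos
                ins = pair.insert_size
                if ins is not None and mate.unique and other.unique:
                    a.template_length = ins if mate.pos <= other.pos else -ins
                out.write(a)


def _placement_from_segment(seg) -> tuple[MatePlacement, str]:
    if seg.is_unmapped:
        status = "ambiguous" if seg.has_tag("ZS") and seg.get_tag("ZS") == "A" else "unmapped"
        seq = seg.query_sequence or ""
        return MatePlacement(status), seq
    clip_left = clip_right = 0
    aln = 0
    cig = seg.cigartuples or [(0, len(seg.query_sequence))]
    for i, (op, n) in enumerate(cig):
        if op == 4:
            if i == 0:
                clip_left = n
            else:
                clip_right = n
        elif op == 0:
            aln += n
    strand = "-" if seg.is_reverse else "+"
    seq = seg.query_sequence
    if seg.is_reverse:
        seq = revcomp(seq)
    return (
        MatePlacement(
            "unique",
            seg.reference_name,
            seg.reference_start,
            strand,
            aln_len=aln,
            clip_left=clip_left,
            clip_right=clip_right,
        ),
        seq,
    )


def read_sam(path) -> list[AlignedPair]:
    """Parse a SAM file back into aligned pairs (mate order restored from
    the first/second-in-pair flags)."""
    by_name: dict[str, AlignedPair] = {}
    order: list[str] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for seg in fh:
            if seg.query_name not in by_name:
                by_name[seg.query_name] = AlignedPair(seg.query_name, "", "")
                order.append(seg.query_name)
            pair = by_name[seg.query_name]
            placement, seq = _placement_from_segment(seg)
            if seg.is_read1 or not seg.is_read2:
                pair.mate1, pair.seq1 = placement, seq
            else:
                pair.mate2, pair.seq2 = placement, seq
    return [by_name[n] for n in order]
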