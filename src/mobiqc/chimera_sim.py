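"""Synthetic WGS generator with MDA-style chimera formation.

The generator emulates whole-genome sequencing of amplified genomic DNA
from an organism whose genome carries multi-copy transposable-element
families (copy numbers spanning one to a few hundred):

* a random multi-chromosome background at a configurable GC content,
  with each family's consensus planted at non-overlapping loci on both
  strands;
* optional planted insertions carrying target-site duplications and
  polyA tails;
* multiple-displacement-amplification (MDA) artefacts: with probability
  ``chimera_rate`` a fragment is chimeric, joining two loci that are
  mostly fewer than 10,000 nt apart through a short complementary
  overlap (microhomology) of 2-21 nt with a mode of 5 — the signature of
  ectopic priming of a nascent strand on a nearby template;
* paired-end read emission in two modes: 100 nt ends from ~500 bp
  inserts ("short") and 250 nt ends from ~350 bp fragments ("long").

Reads are error-free and every emitted read pair traces to exactly one
fragment in the ground truth.

MDA microhomology in a real genome pre-exists at the priming site; here
the generator materialises each junction's shared m-mer at both source
loci of the returned genome (and pins the flanking bases so the overlap
is exactly the drawn length), which keeps every chimera
sequence-consistent with the mapping reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import ElementLibrary, Genome, Interval, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Family:
    """A transposable-element family: consensus length and genomic copy
    number."""

    name: str
    length: int
    copies: int


def default_families() -> tuple[Family, ...]:
    """Twelve families with copy numbers spanning 1-200, echoing the
    range seen for fly transposons (single-copy families up to
    several-hundred-copy LTR elements)."""
    lengths = [1200, 1000, 900, 800, 700, 650, 600, 550, 500, 450, 420, 400]
    copies = [1, 2, 3, 5, 8, 12, 20, 30, 50, 80, 120, 200]
    return tuple(
        Family(f"TE{i + 1:02d}", ln, cp)
        for i, (ln, cp) in enumerate(zip(lengths, copies))
    )


@dataclass
class SimConfig:
    """Full parameterisation of genome, amplification and sequencing.

    Defaults describe the short-read study condition: a ~1.2 Mb
    two-chromosome genome at fly-like 42% GC carrying the twelve default
    element families (~20% element content), 40-fold coverage of 100 nt
    paired ends from 500+/-25 bp inserts, and a 4% per-fragment chimera
    rate. Displacement distances are log-uniform on [1, 10^4] with a 5%
    long-range tail; junction microhomology follows a discrete
    triangular distribution on [2, 21] peaking at 5 (an optional mass at
    0 models blunt joins).
    """

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (700_000, 500_000)
    gc: float = 0.42
    families: tuple[Family, ...] = field(default_factory=default_families)
    chimera_rate: float = 0.04
    displacement_max: int = 10_000
    displacement_tail: float = 0.05
    microhomology_zero_frac: float = 0.0
    microhomology_lo: int = 2
    microhomology_peak: int = 5
    microhomology_hi: int = 21
    microhomology_decay: float = 0.7
    frag_len_mean: float = 500.0
    frag_len_sd: float = 25.0
    read_len: int = 100
    coverage: float = 40.0
    n_fragments: int | None = None
    mode: str = "short"

    def __post_init__(self):
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be a probability")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be a fraction")
        if not 0.0 <= self.microhomology_zero_frac <= 1.0:
            raise ValueError("microhomology_zero_frac must be a probability")
        if not (
            self.microhomology_lo <= self.microhomology_peak <= self.microhomology_hi
        ):
            raise ValueError("microhomology distribution bounds out of order")

    @staticmethod
    def long_mode(**kwargs) -> "SimConfig":
        """Preset for the merged-read condition: 250 nt paired ends from
        350+/-30 bp fragments."""
        kwargs.setdefault("frag_len_mean", 350.0)
        kwargs.setdefault("frag_len_sd", 30.0)
        kwargs.setdefault("read_len", 250)
        kwargs.setdefault("mode", "long")
        return SimConfig(**kwargs)

    def microhomology_pmf(self) -> tuple[np.ndarray, np.ndarray]:
        """Values and probabilities of the junction-overlap distribution:
        optional mass at 0, then a single-peaked distribution on
        [lo, hi] — linear rise to the peak, geometric decay beyond it.

        The geometric right arm mirrors the sharply peaked overlap-size
        distributions observed for amplification chimera; it also keeps
        the peak unambiguous at realistic junction counts, which a flat
        triangular arm over twenty sizes would not.
        """
        lo, pk, hi = self.microhomology_lo, self.microhomology_peak, self.microhomology_hi
        r = self.microhomology_decay
        values = list(range(lo, hi + 1))
        weights = [
            (m - lo + 1) / (pk - lo + 1) if m <= pk else r ** (m - pk)
            for m in values
        ]
        w = np.asarray(weights, dtype=float)
        w = w / w.sum() * (1.0 - self.microhomology_zero_frac)
        if self.microhomology_zero_frac > 0:
            values = [0] + values
            w = np.concatenate([[self.microhomology_zero_frac], w])
        return np.asarray(values, dtype=int), w


@dataclass
class ChimeraJunction:
    """Ground truth for one chimeric joint: the two source loci, the
    effective junction microhomology, and their genomic separation."""

    junction_id: int
    fragment_id: int
    chrom: str
    left_start: int
    left_end: int  # exclusive; the junction position on the left locus
    right_start: int  # the junction position on the right locus
    right_end: int  # exclusive; includes the shared m-mer
    microhomology: int
    m_drawn: int
    distance: int  # |right_start - left_end|; same-chromosome by default
    strand: str = "+"


@dataclass
class Fragment:
    fid: int
    seq: str
    chrom: str
    start: int | None
    end: int | None
    chimeric: bool
    strand: str
    junction_id: int | None = None


@dataclass
class InsertionTruth:
    name: str
    element: str
    chrom: str
    pos: int  # insertion point in pre-insertion coordinates
    tsd_len: int
    polya_len: int
    inserted_len: int


@dataclass
class TruthTable:
    """Planted insertions, all chimeric junctions, and per-fragment
    provenance (read names encode the fragment id)."""

    fragments: list[Fragment] = field(default_factory=list)
    junctions: list[ChimeraJunction] = field(default_factory=list)
    insertions: list[InsertionTruth] = field(default_factory=list)
    n_dropped_short: int = 0

    def junction_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(j) for j in self.junctions])


def random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    length: int,
    occupied: dict[str, list[tuple[int, int]]],
    max_tries: int = 500,
) -> tuple[str, int]:
    import bisect

    names = list(chrom_lengths)
    weights = np.array([chrom_lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    for _ in range(max_tries):
        chrom = names[int(rng.choice(len(names), p=weights))]
        clen = chrom_lengths[chrom]
        if clen <= length:
            continue
        pos = int(rng.integers(0, clen - length + 1))
        occ = occupied[chrom]
        i = bisect.bisect_left(occ, (pos, pos))
        if i > 0 and occ[i - 1][1] > pos:
            continue
        if i < len(occ) and occ[i][0] < pos + length:
            continue
        occ.insert(i, (pos, pos + length))
        return chrom, pos
    raise RuntimeError(
        "could not place element copy without overlap; use longer chromosomes"
    )


def simulate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, list[Interval], ElementLibrary]:
    """Random background genome with element families planted at
    non-overlapping loci (both strands, p = 0.5).

    Returns the genome, the annotated element loci, and the consensus
    library. Deterministic given ``config.seed`` (or the supplied rng).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(len(config.chrom_lengths))]
    seqs = {
        name: bytearray(random_seq(n, config.gc, rng), "ascii")
        for name, n in zip(chrom_names, config.chrom_lengths)
    }
    lengths = dict(zip(chrom_names, config.chrom_lengths))
    library_records = []
    loci: list[Interval] = []
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in chrom_names}
    for fam in config.families:
        consensus = random_seq(fam.length, config.gc, rng)
        library_records.append((fam.name, consensus))
        for _ in range(fam.copies):
            chrom, pos = _place_nonoverlapping(rng, lengths, fam.length, occupied)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = consensus if strand == "+" else revcomp(consensus)
            seqs[chrom][pos : pos + fam.length] = planted.encode()
            loci.append(Interval(chrom, pos, pos + fam.length, fam.name, strand))
    loci.sort(key=lambda iv: (iv.chrom, iv.start))
    genome = Genome([(n, seqs[n].decode()) for n in chrom_names])
    return genome, loci, ElementLibrary(library_records)


def simulate_exon_catalog(
    genome: Genome,
    rng: np.random.Generator,
    n: int = 300,
    min_len: int = 150,
    max_len: int = 2500,
    avoid: list[Interval] = (),
    min_gap: int = 800,
) -> list[Interval]:
    """Random non-overlapping 'exon' intervals on an existing genome,
    avoiding the given loci — the raw material for an immobile-element
    catalogue.

    ``min_gap`` keeps exons at least that far apart so no single
    sequencing fragment can straddle two of them.
    """
    lengths = {name: genome.length(name) for name in genome.names}
    occupied: dict[str, list[tuple[int, int]]] = {name: [] for name in genome.names}
    import bisect

    for iv in avoid:
        occ = occupied[iv.chrom]
        occ.insert(bisect.bisect_left(occ, (iv.start, iv.end)), (iv.start, iv.end))
    out = []
    for i in range(n):
        ln = int(rng.integers(min_len, max_len + 1))
        try:
            chrom, pos = _place_nonoverlapping(rng, lengths, ln + 2 * min_gap, occupied)
        except RuntimeError:
            break
        out.append(Interval(chrom, pos + min_gap, pos + min_gap + ln, f"exon{i:04d}"))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def plant_insertion(
    genome: Genome,
    element_seq: str,
    chrom: str,
    pos: int,
    tsd_len: int = 0,
    polya_len: int = 0,
    name: str = "ins",
    element_name: str = "",
) -> tuple[Genome, InsertionTruth]:
    """Insert ``element_seq`` plus a polyA tail at ``pos``, duplicating
    the ``tsd_len`` nucleotides immediately 5' of the site on both sides
    of the insertion (a target-site duplication).

    The genome grows by ``len(element_seq) + polya_len + tsd_len``.
    """
    if chrom not in genome:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome.seq(chrom)
    if not 0 <= pos <= len(seq):
        raise ValueError("insertion site out of bounds")
    if tsd_len > pos:
        raise ValueError("tsd_len exceeds the sequence 5' of the site")
    tsd = seq[pos - tsd_len : pos]
    new = seq[:pos] + element_seq + "A" * polya_len + tsd + seq[pos:]
    records = [(n, new if n == chrom else s) for n, s in genome.records]
    truth = InsertionTruth(
        name,
        element_name,
        chrom,
        pos,
        tsd_len,
        polya_len,
        len(element_seq) + polya_len + tsd_len,
    )
    return Genome(records), truth


def _sample_displacement(
    rng: np.random.Generator, config: SimConfig, chrom_len: int
) -> int:
    """Log-uniform on [1, displacement_max], with a small long-range tail
    reaching up to half the chromosome."""
    if rng.random() < config.displacement_tail:
        lo, hi = config.displacement_max, max(chrom_len // 2, config.displacement_max + 1)
    else:
        lo, hi = 1, config.displacement_max
    return max(1, int(round(math.exp(rng.uniform(math.log(lo), math.log(hi))))))


def _other_base(b: int, rng: np.random.Generator) -> int:
    choices = [x for x in _BASES.tolist() if x != b]
    return choices[int(rng.integers(0, len(choices)))]


def mda_amplify(
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    n_fragments: int | None = None,
) -> tuple[Genome, list[Fragment], list[ChimeraJunction]]:
    """Draw an amplified fragment pool, a fraction of it chimeric.

    Fragment lengths are Normal(frag_len_mean, frag_len_sd) truncated
    positive at uniform genomic positions; with probability
    ``chimera_rate`` a fragment joins two same-chromosome loci through a
    drawn microhomology. The returned genome carries the materialised
    junction m-mers (see the module docstring) and is the reference every
    downstream stage should map against. Every junction is logged; the
    effective microhomology is re-measured on the final sequence so the
    truth table is exact even if two junction edits collide.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    seqs = {name: bytearray(s, "ascii") for name, s in genome.records}
    lengths = {name: len(s) for name, s in genome.records}
    names = list(lengths)
    weights = np.array([lengths[n] for n in names], dtype=float)
    weights /= weights.sum()
    total = int(sum(lengths.values()))
    if n_fragments is None:
        n_fragments = config.n_fragments
    if n_fragments is None:
        n_fragments = int(round(config.coverage * total / (2 * config.read_len)))
    m_values, m_probs = config.microhomology_pmf()

    plans = []  # (fid, chrom, start, L, strand, chimeric-tuple | None)
    for fid in range(n_fragments):
        L = max(40, int(round(rng.normal(config.frag_len_mean, config.frag_len_sd))))
        chrom = names[int(rng.choice(len(names), p=weights))]
        clen = lengths[chrom]
        if L >= clen:
            L = clen // 2
        strand = "+" if rng.random() < 0.5 else "-"
        chim = None
        if rng.random() < config.chimera_rate:
            m = int(m_values[int(rng.choice(len(m_values), p=m_probs))])
            if L >= m + 8:
                c = int(rng.integers(max(m + 2, 4), L - 2))
                right_len = L - c
                for _ in range(60):
                    start = int(rng.integers(1, clen - L))
                    abreak = start + c
                    d = _sample_displacement(rng, config, clen)
                    # a shared overlap is only well defined when the two
                    # priming sites are farther apart than the overlap
                    # itself (plus its pinned flanks)
                    if d < 2 * m + 2:
                        continue
                    for sign in rng.permutation([1, -1]).tolist():
                        b = abreak + int(sign) * d
                        if 1 <= b and b + right_len + m + 1 <= clen and b != abreak:
                            chim = (c, b, m)
                            break
                    if chim is not None:
                        break
        if chim is not None:
            c, b, m = chim
            abreak = start + c
            s = seqs[chrom]
            if m:
                s[b : b + m] = s[abreak - m : abreak]
            # pin the flanking bases so the dual-assignable overlap is
            # exactly the drawn length
            jpos = b + m
            if jpos < clen and s[jpos] == s[abreak]:
                s[jpos] = _other_base(s[abreak], rng)
            if b - 1 >= 0 and abreak - m - 1 >= 0 and s[b - 1] == s[abreak - m - 1]:
                s[b - 1] = _other_base(s[abreak - m - 1], rng)
            plans.append((fid, chrom, start, L, strand, chim))
        else:
            start = int(rng.integers(0, clen - L + 1))
            plans.append((fid, chrom, start, L, strand, None))

    genome_out = Genome([(n, seqs[n].decode()) for n, _ in genome.records])
    fragments: list[Fragment] = []
    junctions: list[ChimeraJunction] = []
    for fid, chrom, start, L, strand, chim in plans:
        s = seqs[chrom]
        clen = lengths[chrom]
        if chim is None:
            frag_seq = s[start : start + L].decode()
            if strand == "-":
                frag_seq = revcomp(frag_seq)
            fragments.append(Fragment(fid, frag_seq, chrom, start, start + L, False, strand))
            continue
        c, b, m = chim
        abreak = start + c
        contig = bytes(s[start:abreak]) + bytes(s[b + m : b + m + (L - c)])
        # effective overlap measured on the final sequence
        fwd = 0
        while c + fwd < len(contig) and abreak + fwd < clen and contig[c + fwd] == s[abreak + fwd]:
            fwd += 1
        back = 0
        while c - 1 - back >= 0 and b + m - 1 - back >= 0 and contig[c - 1 - back] == s[b + m - 1 - back]:
            back += 1
        # record the maximal-anchor decomposition: the left segment
        # extended by any coincidental forward match, the right segment
        # extended back through the shared overlap — exactly what a
        # breakpoint resolver can recover from the sequence
        left_end = abreak + fwd
        right_start = b + m - back
        jid = len(junctions)
        junctions.append(
            ChimeraJunction(
                junction_id=jid,
                fragment_id=fid,
                chrom=chrom,
                left_start=start,
                left_end=left_end,
                right_start=right_start,
                right_end=b + m + (L - c),
                microhomology=fwd + back,
                m_drawn=m,
                distance=abs(right_start - left_end),
                strand=strand,
            )
        )
        frag_seq = contig.decode()
        if strand == "-":
            frag_seq = revcomp(frag_seq)
        fragments.append(Fragment(fid, frag_seq, chrom, start, None, True, strand, jid))
    return genome_out, fragments, junctions


def generate_reads(
    fragments: list[Fragment], config: SimConfig
) -> tuple[list[tuple[str, str, str]], int]:
    """Emit error-free FR read pairs: mate 1 is the first ``read_len`` nt
    of the fragment, mate 2 the reverse complement of the last
    ``read_len`` nt. Fragments shorter than the read length are dropped
    and counted. Read names encode the fragment id."""
    rl = config.read_len
    pairs = []
    dropped = 0
    for frag in fragments:
        if len(frag.seq) < rl:
            dropped += 1
            continue
        pairs.append((f"frag{frag.fid}", frag.seq[:rl], revcomp(frag.seq[-rl:])))
    return pairs, dropped


def write_fastq_pair(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")


def read_fastq_pair(path1, path2) -> list[tuple[str, str, str]]:
    def _read(path):
        out = []
        with open(path) as fh:
            while True:
                h = fh.readline()
                if not h:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                name = h.strip().lstrip("@").rsplit("/", 1)[0]
                out.append((name, seq))
        return out

    r1, r2 = _read(path1), _read(path2)
    if [n for n, _ in r1] != [n for n, _ in r2]:
        raise ValueError("FASTQ mates are not in matching order")
    return [(n, s1, s2) for (n, s1), (_, s2) in zip(r1, r2)]
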