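"""Simulated-reference construction for immobile-element controls.

An "immobile genetic element" (IGE) is an exon treated as if it were a
transposon. Exons cannot mobilise, so after excising each selected exon
from its native locus and appending it to the end of a designated
chromosome, every excision point must surface as a germline "insertion"
when real reads are aligned to the modified genome — and any additional
IGE call measures the pipeline's false-discovery rate.

Two simulated references are built here:

* **DMsim** — the genome with the IGE set excised and appended; if a
  chromosome read A-B-C and B is an IGE, the modified chromosome reads
  A-C with B moved to the end of the destination chromosome.
* **DMclean** — the genome with every annotated element copy masked to N
  and one consensus of each family concatenated onto a synthetic 'TE'
  chromosome, used for element read counting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import ElementLibrary, Genome, Interval


@dataclass
class IgeProvenance:
    name: str
    source: Interval  # native locus on the input genome
    appended: Interval  # location of the moved copy in DMsim coordinates
    excision_point: Interval  # 1-nt window at the excision site in DMsim


@dataclass
class IgeBuild:
    dmsim: Genome
    ige_library: ElementLibrary
    excision_points: list[Interval]
    provenance: list[IgeProvenance]
    dest_chrom: str


def select_iges(
    catalog: list[Interval], nt_budget: int
) -> tuple[list[Interval], bool]:
    """Greedy size-ranked IGE selection.

    Exons are ranked by length descending (ties by chromosome then start)
    and taken from the top until the cumulative length first reaches or
    exceeds ``nt_budget``; an exon overlapping or book-ended with an
    already-selected exon is skipped. Returns the selection and whether
    the budget was met (False means the catalogue was exhausted first).
    """
    if not catalog:
        raise ValueError("empty exon catalogue")
    if nt_budget <= 0:
        raise ValueError("nt_budget must be positive")
    ranked = sorted(catalog, key=lambda iv: (-iv.length, iv.chrom, iv.start))
    selected: list[Interval] = []
    total = 0
    for exon in ranked:
        clash = any(
            exon.chrom == s.chrom and exon.start <= s.end and s.start <= exon.end
            for s in selected
        )
        if clash:
            continue
        selected.append(exon)
        total += exon.length
        if total >= nt_budget:
            return selected, True
    return selected, False


def build_dmsim(genome: Genome, iges: list[Interval], dest_chrom: str) -> IgeBuild:
    """Excise each IGE from its native locus and append it, in selection
    order, to the end of ``dest_chrom``.

    Excision proceeds high-to-low coordinate per chromosome so earlier
    coordinates stay valid; the genome's total length is unchanged, and
    each excision point is recorded as a 1-nt window in DMsim
    coordinates.
    """
    if dest_chrom not in genome:
        raise KeyError(f"destination chromosome {dest_chrom!r} not in genome")
    by_chrom: dict[str, list[tuple[int, Interval]]] = {}
    names = []
    for i, iv in enumerate(iges):
        if iv.chrom not in genome:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > genome.length(iv.chrom):
            raise ValueError(f"IGE {iv.name or i} exceeds chromosome bounds")
        names.append(iv.name or f"IGE{i:04d}")
        by_chrom.setdefault(iv.chrom, []).append((i, iv))
    if len(set(names)) != len(names):
        raise ValueError("IGE names are not unique")
    for chrom, items in by_chrom.items():
        ivs = sorted((iv for _, iv in items), key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping IGEs on {chrom}")

    source_seqs = {}
    excision_pts = {}  # selection index -> (chrom, point in excised coords)
    new_seqs = {name: genome.seq(name) for name in genome.names}
    for chrom, items in by_chrom.items():
        seq = genome.seq(chrom)
        ascending = sorted(items, key=lambda t: t[1].start)
        shift = 0
        for sel_idx, iv in ascending:
            source_seqs[sel_idx] = seq[iv.start : iv.end]
            excision_pts[sel_idx] = (chrom, iv.start - shift)
            shift += iv.length
        # excise high-to-low so coordinates never invalidate
        out = seq
        for _, iv in sorted(items, key=lambda t: -t[1].start):
            out = out[: iv.start] + out[iv.end :]
        new_seqs[chrom] = out

    base = len(new_seqs[dest_chrom])
    provenance: list[IgeProvenance] = []
    appended_parts = []
    cum = 0
    for sel_idx, iv in enumerate(iges):
        ige_seq = source_seqs[sel_idx]
        appended = Interval(dest_chrom, base + cum, base + cum + iv.length, names[sel_idx])
        cum += iv.length
        appended_parts.append(ige_seq)
        chrom, p = excision_pts[sel_idx]
        p = min(p, len(new_seqs[chrom]) - 1) if chrom != dest_chrom else p
        provenance.append(
            IgeProvenance(
                names[sel_idx],
                iv,
                appended,
                Interval(chrom, p, p + 1, names[sel_idx]),
            )
        )
    new_seqs[dest_chrom] = new_seqs[dest_chrom] + "".join(appended_parts)

    dmsim = Genome([(n, new_seqs[n]) for n in genome.names])
    library = ElementLibrary(
        [(names[i], source_seqs[i]) for i in range(len(iges))]
    )
    return IgeBuild(
        dmsim=dmsim,
        ige_library=library,
        excision_points=[p.excision_point for p in provenance],
        provenance=provenance,
        dest_chrom=dest_chrom,
    )


def reinsert_iges(build: IgeBuild, genome_names: list[str] | None = None) -> Genome:
    """Invert :func:`build_dmsim` using the recorded provenance: strip the
    appended block and re-insert every IGE at its excision point."""
    seqs = {n: build.dmsim.seq(n) for n in build.dmsim.names}
    appended_total = sum(p.appended.length for p in build.provenance)
    if appended_total:
        seqs[build.dest_chrom] = seqs[build.dest_chrom][:-appended_total]
    by_chrom: dict[str, list[IgeProvenance]] = {}
    for p in build.provenance:
        by_chrom.setdefault(p.source.chrom, []).append(p)
    for chrom, items in by_chrom.items():
        seq = seqs[chrom]
        # recompute unclamped excision coordinates, then restore
        # high-to-low so earlier points stay valid
        ascending = sorted(items, key=lambda t: t.source.start)
        shift = 0
        points = []
        for p in ascending:
            points.append((p.source.start - shift, p))
            shift += p.source.length
        for point, p in sorted(points, key=lambda t: -t[0]):
            ige_seq = build.ige_library.seq(p.name)
            seq = seq[:point] + ige_seq + seq[point:]
        seqs[chrom] = seq
    return Genome([(n, seqs[n]) for n in build.dmsim.names])


def build_dmclean(
    genome: Genome,
    elements: ElementLibrary,
    element_loci: list[Interval],
    te_chrom: str = "TE",
) -> tuple[Genome, list[Interval]]:
    """Mask every annotated element locus to N and append a 'TE'
    chromosome carrying each library element exactly once.

    Returns the masked genome and the interval list locating each element
    on the TE chromosome.
    """
    if te_chrom in genome:
        raise ValueError(f"genome already has a chromosome named {te_chrom!r}")
    seqs = {n: bytearray(genome.seq(n), "ascii") for n in genome.names}
    for iv in element_loci:
        if iv.chrom not in seqs:
            raise KeyError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > len(seqs[iv.chrom]):
            raise ValueError(f"element locus {iv.name} exceeds chromosome bounds")
        seqs[iv.chrom][iv.start : iv.end] = b"N" * iv.length
    te_intervals = []
    pos = 0
    te_parts = []
    for name, seq in elements.records:
        te_intervals.append(Interval(te_chrom, pos, pos + len(seq), name, "+"))
        te_parts.append(seq)
        pos += len(seq)
    records = [(n, seqs[n].decode()) for n in genome.names]
    records.append((te_chrom, "".join(te_parts)))
    return Genome(records), te_intervals


def expected_germline_junctions(build: IgeBuild, window: int = 250) -> list[Interval]:
    """One expected-call window per IGE, centred on its excision point
    and clipped to the chromosome; the window width is the caller's
    positional tolerance."""
    out = []
    for p in build.provenance:
        ep = p.excision_point
        clen = build.dmsim.length(ep.chrom)
        out.append(
            Interval(
                ep.chrom,
                max(0, ep.start - window),
                min(clen, ep.end + window),
                p.name,
            )
        )
    return out
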