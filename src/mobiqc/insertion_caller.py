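"""Discordant-read-pair insertion calling.

The primary evidence for a non-reference element insertion is a read
pair in which one mate anchors the genome uniquely while the other mate
lies inside an element consensus. Same-element anchors are clustered by
single linkage into calls; each call carries 5'/3' support counts, a
penetrance estimate (supporting reads against reference-spanning pairs),
and — across samples — a germline-shared vs sample-specific class.

Calls landing at annotated genomic copies of the same element are the
expected signature of reads sampled from those copies, not of new
insertions; :func:`split_reference_calls` separates them so that only
non-reference calls enter artefact and comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import ElementLibrary, Genome, Interval, flank_intervals, subtract_overlapping
from .micromap import AlignedPair, ElementClassifier


@dataclass
class DiscordantPair:
    """One element-insertion evidence pair: the genome-anchored mate and
    the element classification of its partner."""

    read_id: str
    anchor_chrom: str
    anchor_pos: int
    anchor_strand: str
    element: str
    side: str  # 5p when the anchor points at the insertion from the left


@dataclass
class InsertionCall:
    element: str
    chrom: str
    start: int
    end: int
    support_5p: int
    support_3p: int
    sample_id: str = ""
    reference_spanning: int = 0
    penetrance: float | None = None
    call_class: str = "sample-specific"
    read_ids: list[str] = field(default_factory=list)

    @property
    def support_total(self) -> int:
        return self.support_5p + self.support_3p

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.element)


def estimate_insert_range(
    pairs: list[AlignedPair], lo_pct: float = 5.0, hi_pct: float = 95.0
) -> tuple[int, int]:
    """Central 90% interval of the proper-pair insert-size distribution."""
    sizes = []
    for p in pairs:
        m1, m2 = p.mate1, p.mate2
        if (
            m1.unique
            and m2.unique
            and not m1.clipped
            and not m2.clipped
            and m1.chrom == m2.chrom
            and m1.strand != m2.strand
        ):
            left = m1 if m1.pos <= m2.pos else m2
            if left.strand == "+":
                sizes.append(p.insert_size)
    if not sizes:
        raise ValueError("no proper pairs to estimate the insert range from")
    arr = np.asarray(sizes)
    return int(np.percentile(arr, lo_pct)), int(np.ceil(np.percentile(arr, hi_pct)))


def find_discordant(
    pairs: list[AlignedPair],
    elements: ElementLibrary,
    insert_range: tuple[int, int],
    k: int = 21,
    classifier: ElementClassifier | None = None,
) -> list[DiscordantPair]:
    """Scan aligned pairs for element-insertion evidence.

    A pair is discordant when it is not a proper pair within
    ``insert_range``. Of the discordant pairs, those with exactly one
    mate classifying to an element family and the other mate
    unique-mapped to the genome are returned; the anchor strand assigns
    the 5'/3' side. Ambiguous anchors never contribute evidence.
    """
    if len(elements) == 0:
        raise ValueError("empty element library")
    if classifier is None:
        classifier = ElementClassifier(elements, k)
    lo, hi = insert_range
    out: list[DiscordantPair] = []
    for pair in pairs:
        if pair.concordant(lo, hi):
            continue
        el1, amb1 = classifier.classify(pair.seq1)
        el2, amb2 = classifier.classify(pair.seq2)
        if amb1 or amb2:
            continue
        if (el1 is None) == (el2 is None):  # both or neither classified
            continue
        element = el1 or el2
        anchor = pair.mate2 if el1 else pair.mate1
        if not anchor.unique:
            continue
        out.append(
            DiscordantPair(
                read_id=pair.name,
                anchor_chrom=anchor.chrom,
                anchor_pos=anchor.pos,
                anchor_strand=anchor.strand,
                element=element,
                side="5p" if anchor.strand == "+" else "3p",
            )
        )
    return out


def cluster_calls(
    discordant: list[DiscordantPair],
    window: int,
    read_len: int,
    min_support: int = 1,
    sample_id: str = "",
) -> list[InsertionCall]:
    """Single-linkage clustering of same-element anchors within
    ``window`` nt on one chromosome.

    The call window is [min anchor, max anchor + read length); calls
    below ``min_support`` are dropped; output order is deterministic
    (chrom, start, element).
    """
    groups: dict[tuple[str, str], list[DiscordantPair]] = {}
    for d in discordant:
        groups.setdefault((d.element, d.anchor_chrom), []).append(d)
    calls: list[InsertionCall] = []
    for (element, chrom), items in groups.items():
        items.sort(key=lambda d: d.anchor_pos)
        cluster: list[DiscordantPair] = []
        for d in items:
            if cluster and d.anchor_pos - cluster[-1].anchor_pos > window:
                calls.append(_make_call(cluster, element, chrom, read_len, sample_id))
                cluster = []
            cluster.append(d)
        if cluster:
            calls.append(_make_call(cluster, element, chrom, read_len, sample_id))
    calls = [c for c in calls if c.support_total >= min_support]
    calls.sort(key=lambda c: (c.chrom, c.start, c.element))
    return calls


def _make_call(cluster, element, chrom, read_len, sample_id) -> InsertionCall:
    s5 = sum(1 for d in cluster if d.side == "5p")
    s3 = len(cluster) - s5
    return InsertionCall(
        element=element,
        chrom=chrom,
        start=cluster[0].anchor_pos,
        end=cluster[-1].anchor_pos + read_len,
        support_5p=s5,
        support_3p=s3,
        sample_id=sample_id,
        read_ids=[d.read_id for d in cluster],
    )


class _SpanIndex:
    """Per-chromosome arrays of concordant-pair inner spans for fast
    midpoint-crossing counts."""

    def __init__(self, pairs: list[AlignedPair], insert_range: tuple[int, int]):
        lo, hi = insert_range
        spans: dict[str, list[tuple[int, int]]] = {}
        for p in pairs:
            if not p.concordant(lo, hi):
                continue
            m1, m2 = p.mate1, p.mate2
            left, right = (m1, m2) if m1.pos <= m2.pos else (m2, m1)
            spans.setdefault(left.chrom, []).append((left.end, right.pos))
        self._by_chrom = {
            chrom: (
                np.array([s for s, _ in items], dtype=np.int64),
                np.array([e for _, e in items], dtype=np.int64),
            )
            for chrom, items in spans.items()
        }

    def crossing(self, chrom: str, pos: int) -> int:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return 0
        starts, ends = entry
        return int(np.count_nonzero((starts <= pos) & (ends > pos)))


def estimate_penetrance(
    calls: list[InsertionCall],
    pairs: list[AlignedPair],
    insert_range: tuple[int, int],
) -> list[InsertionCall]:
    """Fill reference_spanning and penetrance for each call.

    Reference-spanning pairs are concordant unique pairs whose inner
    span (between the facing mate ends) fully crosses the call-window
    midpoint. Penetrance is support / (support + spanning); with a zero
    denominator it is left undefined rather than forced to 1.
    """
    index = _SpanIndex(pairs, insert_range)
    for call in calls:
        call.reference_spanning = index.crossing(call.chrom, call.midpoint)
        denom = call.support_total + call.reference_spanning
        call.penetrance = call.support_total / denom if denom > 0 else None
    return calls


def split_reference_calls(
    calls: list[InsertionCall], element_loci: list[Interval], pad: int = 250
) -> tuple[list[InsertionCall], list[InsertionCall]]:
    """Separate calls at annotated same-element genomic copies
    (reference calls) from putative non-reference insertions."""
    by_element: dict[str, list[Interval]] = {}
    for iv in element_loci:
        by_element.setdefault(iv.name, []).append(iv)
    novel, reference = [], []
    for call in calls:
        loci = by_element.get(call.element, [])
        at_copy = any(
            iv.chrom == call.chrom
            and call.start < iv.end + pad
            and iv.start - pad < call.end
            for iv in loci
        )
        (reference if at_copy else novel).append(call)
    return novel, reference


def compare_samples(
    calls_a: list[InsertionCall],
    calls_b: list[InsertionCall],
    pad: int = 250,
    genome: Genome | None = None,
) -> list[InsertionCall]:
    """Calls in ``a`` with no positional overlap against ``b``'s windows
    flanked by ``pad`` nt on each side (element identity is ignored; the
    flank compensates for breakpoint-position uncertainty)."""
    b_iv = [c.interval() for c in calls_b]
    if genome is not None:
        b_flanked = flank_intervals(b_iv, pad, genome)
    else:
        b_flanked = [
            Interval(iv.chrom, max(0, iv.start - pad), iv.end + pad, iv.name)
            for iv in b_iv
        ]
    kept_iv = subtract_overlapping([c.interval() for c in calls_a], b_flanked)
    kept_keys = {(iv.chrom, iv.start, iv.end, iv.name) for iv in kept_iv}
    return [
        c
        for c in calls_a
        if (c.chrom, c.start, c.end, c.element) in kept_keys
    ]


def classify_germline(
    call_sets: dict[str, list[InsertionCall]], pad: int = 250
) -> dict[str, list[InsertionCall]]:
    """Annotate calls as germline-shared (same-element, pad-overlap
    support present in every sample) or sample-specific.

    With a single sample every call is sample-specific (nothing to
    corroborate against)."""
    samples = list(call_sets)
    if len(samples) < 2:
        for calls in call_sets.values():
            for c in calls:
                c.call_class = "sample-specific"
        return call_sets
    for sample, calls in call_sets.items():
        others = [s for s in samples if s != sample]
        for call in calls:
            shared = all(
                any(
                    o.element == call.element
                    and o.chrom == call.chrom
                    and call.start < o.end + pad
                    and o.start - pad < call.end
                    for o in call_sets[other]
                )
                for other in others
            )
            call.call_class = "germline-shared" if shared else "sample-specific"
    return call_sets
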