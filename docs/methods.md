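# Methods

## Overview

`mobiqc` quantifies how much of the discordant-read-pair signal used to
call rare transposable-element (TE) insertions is produced by chimeric
molecules formed during whole-genome amplification. It does so with
three interlocking components: a ground-truthed simulator of
MDA-amplified paired-end sequencing, an immobile-genetic-element (IGE)
control built from the reference genome itself, and a merged-read
pipeline that resolves breakpoint junctions at nucleotide resolution.

## The chimera model

A sequencing fragment is chimeric with probability `chimera_rate`
(default 0.04 per fragment, chosen to echo the few-percent excess of
long-insert pairs seen in amplified fly libraries; every analysis
accepts other rates). A chimeric fragment joins two same-chromosome
loci:

* **Displacement.** The distance between the junction-adjacent ends of
  the two source segments is log-uniform on [1, 10⁴] nt with a 5%
  long-range tail reaching half the chromosome. This encodes the
  observation that strand-displacement amplification re-primes mostly
  on nearby templates; it is the mechanism behind artefact "hovering"
  around germline element copies.
* **Microhomology.** The junction carries a complementary overlap of
  *m* nt assignable to both sides. *m* is drawn from a single-peaked
  discrete distribution on [2, 21]: linear rise to the peak at 5, then
  geometric decay with ratio 0.7 per nt. The bounds and mode follow the
  reported behaviour of MDA chimera; the geometric right arm reflects
  the sharply peaked overlap-size distributions seen in that data and
  keeps the mode statistically unambiguous at realistic junction
  counts (a flat triangular arm over twenty sizes would not). An
  optional probability mass at *m* = 0 models blunt joins; it defaults
  to 0 because the non-overlap junction structure of real chimera is
  not characterised.
* **Sequence consistency.** In a real genome the shared *m*-mer
  pre-exists at both loci — that is why priming happens there. The
  simulator inverts this: it draws the junction first and then
  materialises the left segment's terminal *m*-mer at the start of the
  right locus in the returned genome, pinning the two flanking bases so
  the dual-assignable overlap is *exactly* the drawn length. The
  returned genome is therefore the mapping reference for every
  downstream stage, and each truth record stores the maximal-anchor
  decomposition (left segment, right segment, overlap, separation) that
  a breakpoint resolver can actually recover. Displacements smaller
  than 2·*m* + 2 are resampled, since a junction overlap is only well
  defined when the priming sites are farther apart than the overlap
  plus its pinned flanks.

Fragment lengths are Normal (500 ± 25 bp in the 100 nt short-read mode,
350 ± 30 bp in the 250 nt long-read mode — the two supported library
geometries), truncated at 40 bp. Reads are error-free, FR-oriented,
named by fragment id; fragments shorter than the read length are
dropped and counted. The fragment count is
`coverage × genome / (2 × read length)` — i.e. nominal coverage ignores
mate overlap in the long mode.

## The synthetic genome

Random background at 42% GC (fly-like) over two chromosomes totalling
1.2 Mb by default, carrying twelve element families whose copy numbers
span 1–200 and lengths 400–1200 nt (~20% element content) — the copy
range and genome fraction of fly TEs at 1/100 scale. Family copies are
planted verbatim (both strands, p = 0.5) at uniform non-overlapping
loci. Optional planted insertions add target-site duplications
(duplicating the `tsd_len` bases 5′ of the site) and polyA tails.
The synthetic exon catalogue used for IGE builds places exons at least
800 nt apart so that no single fragment can straddle two IGEs; real
exons can be book-ended, and such neighbourhoods would contribute a
small extra artefact class that this generator deliberately excludes
from the clean-data baseline.

What the generator does **not** emulate: sequencing error and quality
scores, PCR duplicates, GC-coverage bias, diverged (non-identical)
element copies, nested or truncated insertions, and inter-chromosomal
chimera (off by default; the modelled evidence is intra-chromosomal).
Passing tests therefore demonstrate correctness of the machinery and
behaviour of the statistics under the stated model, not performance on
diverged repeats or noisy reads — for real data the SAM ingestion path
replaces the built-in exact mapper.

## Mapping and calling

The internal mapper is exact-match by design: reads are error-free, so
seeding the first 21-mer and verifying full-length identity is complete
(position recall 1 on unique loci) and fully deterministic. Reads
failing full-length placement fall back to the longest exact
prefix/suffix anchor ≥ k, recorded as a soft-clipped placement — the
behaviour junction-spanning reads show under a real aligner. Ties
between equally long anchors are never broken arbitrarily: the read is
flagged ambiguous and excluded from evidence.

A pair is discordant when it is not a proper FR pair within the central
90% of the insert-size distribution (estimated per sample). Evidence
pairs have exactly one mate classifying to an element family (exact
containment, either strand; reads present in more than one family are
flagged ambiguous and discarded) and the other mate uniquely anchored.
Same-element anchors within one insert-size of each other are merged by
single linkage; the call window is [min anchor, max anchor + read
length). The default support threshold is a single diagnostic read —
the regime in which chimera dominate — and the support count is emitted
so stricter thresholds can be applied post hoc.

**Reference-copy filtering.** Reads sampled from an annotated germline
element copy inevitably produce "insertion" evidence at that copy;
calls overlapping (±250 nt) a same-element annotated locus are
classed as reference calls and separated from the novel calls that
enter artefact statistics. The appended IGE block in DMsim is treated
identically — it is the reference copy of every IGE.

**Penetrance** is support / (support + concordant pairs whose inner
span crosses the call-window midpoint); with a zero denominator it is
undefined rather than 1. This operationalises the qualitative notion of
insertion frequency; any monotone alternative would order calls the
same way.

## The IGE control

Exons ranked by length (ties by position) are taken greedily until the
cumulative length first reaches the nucleotide budget, skipping
overlapping or book-ended candidates; excision proceeds high-to-low
coordinate per chromosome so coordinates never invalidate, and the
excised sequences are appended in selection order to the destination
chromosome. The build records per-IGE provenance and is exactly
invertible. Sensitivity = recovered excision-point junctions /
expected; every IGE call not at an expected junction is an artefact —
the per-sample false-discovery readout.

## The merged-read pipeline

Mate 2 is reverse-complemented and the longest end-overlap ≥ 10 nt with
zero mismatches (configurable for noisy data) merges the pair; a tie
between equally long valid overlaps leaves the pair unmerged
(determinism over yield). Contigs shorter than 250 nt are dropped and
the fraction reported. Each kept contig yields one synthetic pair from
its first 250 nt (two 100 nt pieces around a 50 nt gap; a centred
window is available) — so a junction in the unfragmented tail of a long
contig goes unflagged, which is the price of fixed geometry. Any
synthetic pair that does not map as a clean, full-length, FR pair
spanning exactly 250 reference nt flags its contig.

Breakpoint resolution finds the longest exact prefix and suffix anchors
of the contig over both strands (candidate ties broken by coordinate
for determinism; junctions closer than the 21 nt seed to a contig end
are counted unresolved). Microhomology is the anchor overlap in contig
coordinates; anchors that leave unmatched middle bases produce a
separate "gap" record (novel bases at the junction), kept out of the
overlap histogram. Every resolved record reassembles its contig byte
for byte: left segment + right segment minus the shared overlap. The
headline overlap histogram reports sizes ≥ 2 — overlaps of 0–1 nt are
not meaningful junction signatures — with the full histogram in the
machine output.

## Statistics

* **Abundance null.** Under random sampling, artefact counts per family
  are proportional to genomic element nucleotides; the regression of
  log₁₀ counts on log₁₀ (element nt × coverage / read length) should
  have slope ≈ 1. Zeros are excluded (no pseudocounts); rescaling
  either axis leaves the slope unchanged.
* **Hovering.** Signed distance from each novel call's window midpoint
  to the nearest edge of a same-element germline copy; the summary
  reports the median absolute distance and the fraction within 10 kb.
* **FPKM** counts each pair once by its leftmost unique mate.
* **Depth normalisation** is linear scaling, with seeded read
  subsampling available when reads are in hand; upscaling is flagged.
* **ΔΔCt.** Target Ct minus the geometric mean housekeeping Ct per
  replicate; fold change 2^(−ΔΔCt) with bounds at ±1 combined SEM.
  Note the bounds are 1-σ: they cover the true fold at roughly the 68%
  rate, which the calibration test asserts.

## Problem sizes

The shipped tests and the acceptance script use: a 3 Mb single
chromosome with 8,000 all-chimeric long-read fragments for junction
recovery (≥ 5,000 resolved junctions; the large genome keeps
independent junction edits from colliding); the default 1.2 Mb /
twelve-family genome at 40× (acceptance benchmark) or 15–20× (multi-
seed regression and hovering checks); and 400 kb genomes at 40× for the
five-seed IGE audits. These sizes give stable statistics in minutes on
one CPU; all scale linearly if increased.

## Known limitations

Exact-match mapping cannot place reads from diverged element copies —
real libraries should be aligned externally and ingested as SAM. The
chimera model joins same-strand segments by default (an inverted-join
option exists; which dominates in real MDA is not established). The
simulator's genome edits that materialise junction overlaps mutate up
to *m* + 2 bases at the acceptor locus, a negligible (<0.5%) fraction
of the genome at default rates but visible as local signal loss at very
high chimera rates on small genomes. Penetrance is undefined in the
long-read mode (mates overlap, so no pair has an inner span).
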