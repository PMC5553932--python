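# mobiqc

Quality control for rare transposon-insertion calling from whole-genome
sequencing.

## The problem

Somatic transposable-element (TE) insertions are detected almost
exclusively from **discordant read pairs**: one mate maps inside a TE
consensus, the other anchors the genome and names the putative insertion
locus. The trouble is that amplified gDNA libraries — in particular
those prepared by multiple-displacement amplification (MDA) from small
cell populations — contain **chimeric molecules**: two genomic segments
joined during amplification through a short complementary overlap
(microhomology, typically 2–21 nt with a mode of 5). When one half of a
chimera lies inside a germline TE copy, the resulting read pair is
indistinguishable from a genuine de novo insertion. Because chimeric
partners sit mostly within ~10 kb of each other, the artefacts even
cluster around existing TE copies ("hovering"), mimicking local
retrotransposition.

`mobiqc` is for anyone calling rare insertions from short-read WGS who
needs to know how much of their signal is amplification artefact. It
provides:

* **Immobile genetic elements (IGEs)** — exons treated as if they were
  transposons. Exons cannot mobilise, so after excising each selected
  exon from the reference and appending it to a chromosome end (the
  *DMsim* genome), every excision point must reappear as a germline
  "insertion" (a sensitivity control), and any *additional* IGE call
  measures the false-discovery rate of the whole pipeline on that
  sample.
* **An explicit MDA-chimera simulator** with full ground truth: genome
  with multi-copy element families, fragments joined at a drawn
  microhomology *m* with displacement distances mostly below 10 kb,
  error-free paired reads in a 100 nt / 500 bp-insert mode and a
  250 nt / 350 bp-fragment mode.
* **A discordant-pair insertion caller** (single-linkage clustering of
  same-element anchors, support counts, penetrance = support /
  (support + reference-spanning pairs), ±250 bp sample comparison,
  germline-shared classification).
* **A merged-read breakpoint pipeline**: overlapping 250 nt mates are
  merged into full-length contigs, refragmented in silico into 100 nt
  pairs spanning exactly 250 nt, and every pair that maps further apart
  than 250 nt flags its contig for nucleotide-resolution breakpoint
  resolution — two segments, their genomic separation, and the length
  of the complementary overlap shared by both sides of the junction.
* **Derived statistics**: the log-log regression of per-element artefact
  counts against normalised element abundance (slope ≈ 1 is the
  signature of random genome sampling), hovering profiles, FPKM element
  quantification on a masked *DMclean* reference, depth normalisation,
  pooled-sample detection odds (30 flies × 1800 cells × ploidy 2 =
  108,000 locus copies; at 25× only 1 in 4,320 events is visible), and a
  2^(−ΔΔCt) fold-change utility.

## Worked example

```python
from mobiqc import chimera_sim as cs, pipeline as pl

# IGE audit: clean vs chimeric amplification of the same genome
for rate in (0.0, 0.04):
    rep = pl.run_ige_audit(seed=1, coverage=40.0, chimera_rate=rate)
    m = rep["metrics"]
    print(f"chimera_rate={rate:.2f}: {m.n_recovered}/{m.n_expected} IGE junctions "
          f"recovered (sensitivity {m.sensitivity:.2f}), {m.n_artefact} artefactual IGE calls")

# merged-read junction audit on a 10%-chimeric long-read library
sim = cs.SimConfig.long_mode(seed=1, chrom_lengths=(1_000_000,), families=(),
                             chimera_rate=0.10, n_fragments=20_000)
rep = pl.run_junction_audit(sim)
st = rep["junction_stats"]
print(f"merged {rep['n_merged']} pairs; {rep['n_exact_250']}/{rep['n_synthetic_pairs']} "
      f"synthetic pairs span exactly 250 nt; {st['n_resolved']} junctions resolved")
print(f"modal microhomology {st['modal_microhomology']} nt, "
      f"median inter-fragment distance {st['median_distance']:.0f} nt")
```

prints

```
chimera_rate=0.00: 19/19 IGE junctions recovered (sensitivity 1.00), 0 artefactual IGE calls
chimera_rate=0.04: 19/19 IGE junctions recovered (sensitivity 1.00), 104 artefactual IGE calls
merged 19989 pairs; 18516/19989 synthetic pairs span exactly 250 nt; 1401 junctions resolved
modal microhomology 5 nt, median inter-fragment distance 491 nt
```

Reading: on chimera-free data the pipeline recovers every expected
germline IGE junction and reports zero artefacts; adding a 4% chimera
rate leaves sensitivity untouched but produces over a hundred IGE
"insertions" that cannot be real — a direct readout of the sample's
false-discovery rate. In the long-read audit, ~7% of the fixed-geometry
250 nt pairs map further apart than they should; the resolved junctions
peak at a 5 nt complementary overlap, the MDA signature.

A `mobiqc` console command exposes the same stages
(`simulate | map | call | compare | ige-build | mrtemp | qc-report |
bench`); see `mobiqc --help`.

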