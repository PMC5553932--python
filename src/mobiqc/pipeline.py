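"""End-to-end orchestration of the simulated benchmarks.

All randomness flows from one seed: each stage draws from a child
generator spawned from the run seed, so identical configurations yield
byte-identical outputs regardless of which stages are enabled
downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import chimera_sim as cs
from . import ige_builder as ib
from . import insertion_caller as ic
from . import mrtemp as mr
from . import stats_qc as sq
from .core_io import Genome, Interval
from .micromap import AlignedPair, Mapper

logger = logging.getLogger("mobiqc")


@dataclass
class RunConfig:
    """Benchmark parameterisation: the simulation condition plus caller
    and comparison settings."""

    sim: cs.SimConfig = field(default_factory=cs.SimConfig)
    k: int = 21
    min_support: int = 1
    pad: int = 250
    sample_id: str = "S1"

    @property
    def seed(self) -> int:
        return self.sim.seed


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def call_sample(
    aligned: list[AlignedPair],
    elements,
    read_len: int,
    sample_id: str = "S",
    min_support: int = 1,
    insert_range: tuple[int, int] | None = None,
    k: int = 21,
) -> tuple[list[ic.InsertionCall], tuple[int, int]]:
    """Insert-range estimation, discordant-pair scan, clustering and
    penetrance for one sample's alignments."""
    if insert_range is None:
        insert_range = ic.estimate_insert_range(aligned)
    disc = ic.find_discordant(aligned, elements, insert_range, k=k)
    calls = ic.cluster_calls(
        disc, window=insert_range[1], read_len=read_len,
        min_support=min_support, sample_id=sample_id,
    )
    calls = ic.estimate_penetrance(calls, aligned, insert_range)
    return calls, insert_range


def simulate_sample(
    sim: cs.SimConfig, rngs: list[np.random.Generator] | None = None
) -> dict:
    """Simulate genome, amplification and reads; returns the stage
    products keyed by name."""
    if rngs is None:
        rngs = _stage_rngs(sim.seed, 3)
    genome, loci, library = cs.simulate_genome(sim, rngs[0])
    reference, fragments, junctions = cs.mda_amplify(genome, sim, rngs[1])
    pairs, dropped = cs.generate_reads(fragments, sim)
    return {
        "reference": reference,
        "element_loci": loci,
        "library": library,
        "fragments": fragments,
        "junctions": junctions,
        "read_pairs": pairs,
        "n_dropped_short": dropped,
    }


def run_simulated_benchmark(config: RunConfig) -> dict:
    """The short-read benchmark: simulate -> map -> call -> audit.

    The report separates reference calls (at annotated element copies)
    from novel calls — with no planted insertions every novel call is an
    amplification artefact — then profiles artefact hovering around
    germline copies and regresses per-element artefact counts against
    normalised element abundance.
    """
    sim = config.sim
    logger.info("benchmark: seed=%d genome=%s", sim.seed, sim.chrom_lengths)
    sample = simulate_sample(sim)
    reference = sample["reference"]
    loci = sample["element_loci"]
    library = sample["library"]

    logger.info("mapping %d read pairs", len(sample["read_pairs"]))
    mapper = Mapper(reference, config.k)
    aligned = mapper.map_pairs(sample["read_pairs"])
    calls, insert_range = call_sample(
        aligned,
        library,
        sim.read_len,
        sample_id=config.sample_id,
        min_support=config.min_support,
        k=config.k,
    )
    novel, at_reference = ic.split_reference_calls(calls, loci, pad=config.pad)
    hovering = sq.hovering_profile(novel, loci)

    per_element: dict[str, int] = {}
    for call in novel:
        per_element[call.element] = per_element.get(call.element, 0) + 1
    abundance = {
        fam.name: fam.length * fam.copies * sim.coverage / sim.read_len
        for fam in sim.families
    }
    regression = None
    try:
        fit = sq.loglog_abundance_regression(abundance, per_element)
        regression = vars(fit)
    except ValueError:
        pass

    return {
        "seed": sim.seed,
        "genome_bp": reference.total_length,
        "n_fragments": len(sample["fragments"]),
        "n_chimeric": sum(1 for f in sample["fragments"] if f.chimeric),
        "n_read_pairs": len(sample["read_pairs"]),
        "insert_range": list(insert_range),
        "n_calls_total": len(calls),
        "n_reference_calls": len(at_reference),
        "n_novel_calls": len(novel),
        "per_element_counts": per_element,
        "abundance": abundance,
        "hovering": {k: v for k, v in hovering.items() if k != "distances"},
        "hovering_distances": hovering["distances"],
        "abundance_regression": regression,
        "calls": novel,
    }


def run_junction_audit(sim: cs.SimConfig, k: int = 21) -> dict:
    """The merged-read (long mode) audit: merge pairs, refragment to
    fixed 250 nt inserts, map, flag pairs spanning other than 250
    reference nt, resolve their parent contigs and summarise the
    junctions."""
    if sim.read_len < 150:
        logger.warning("junction audit expects the long-read mode")
    sample = simulate_sample(sim)
    reference = sample["reference"]

    contigs, unmerged = mr.merge_pairs(sample["read_pairs"])
    synthetic, dropped_frac, contig_map = mr.insilico_fragment(contigs)
    mapper = Mapper(reference, k)
    aligned = mapper.map_pairs(synthetic)
    flagged = []
    n_exact = 0
    for pair in aligned:
        clean = (
            pair.mate1.unique
            and pair.mate2.unique
            and not pair.mate1.clipped
            and not pair.mate2.clipped
            and pair.insert_size == 250
            and pair.mate1.strand != pair.mate2.strand
        )
        if clean:
            n_exact += 1
        else:
            flagged.append(pair.name)
    records = [
        mr.resolve_breakpoint(contig_map[cid], mapper.index, sample["element_loci"])
        for cid in flagged
    ]
    stats = mr.junction_statistics(records)
    return {
        "seed": sim.seed,
        "n_fragments": len(sample["fragments"]),
        "n_merged": len(contigs),
        "n_unmerged": len(unmerged),
        "dropped_short_frac": dropped_frac,
        "n_synthetic_pairs": len(aligned),
        "n_exact_250": n_exact,
        "n_flagged": len(flagged),
        "junction_stats": stats,
        "records": records,
        "truth_junctions": sample["junctions"],
        "reference": reference,
        "contig_map": contig_map,
    }


def run_ige_audit(
    seed: int,
    chrom_lengths: tuple[int, ...] = (400_000,),
    coverage: float = 40.0,
    chimera_rate: float = 0.0,
    n_exons: int = 300,
    nt_budget: int = 40_000,
    pad: int = 250,
    k: int = 21,
    sample_id: str = "S1",
) -> dict:
    """The immobile-element control experiment on a synthetic genome.

    Reads are simulated from the original genome and aligned to the
    modified reference with the IGEs excised; every excision point
    should surface as a germline IGE call, and any additional IGE call
    is an artefact.
    """
    sim = cs.SimConfig(
        seed=seed,
        chrom_lengths=chrom_lengths,
        families=(),
        chimera_rate=chimera_rate,
        coverage=coverage,
    )
    rngs = _stage_rngs(seed, 4)
    genome, _, _ = cs.simulate_genome(sim, rngs[0])
    exons = cs.simulate_exon_catalog(genome, rngs[3], n=n_exons)
    iges, met_budget = ib.select_iges(exons, nt_budget)
    reference, fragments, junctions = cs.mda_amplify(genome, sim, rngs[1])
    build = ib.build_dmsim(reference, iges, dest_chrom=genome.names[0])
    pairs, _ = cs.generate_reads(fragments, sim)

    mapper = Mapper(build.dmsim, k)
    aligned = mapper.map_pairs(pairs)
    calls, insert_range = call_sample(
        aligned, build.ige_library, sim.read_len, sample_id=sample_id, k=k
    )
    # the appended block is the reference copy of each IGE; calls there
    # are reference calls, not evidence of mobilisation
    appended = [p.appended for p in build.provenance]
    calls, _ = ic.split_reference_calls(calls, appended, pad=pad)
    if appended:
        block = Interval(
            appended[0].chrom,
            min(a.start for a in appended),
            max(a.end for a in appended),
        )
        calls = [
            c
            for c in calls
            if not (
                c.chrom == block.chrom
                and c.start < block.end + pad
                and block.start - pad < c.end
            )
        ]
    expected = ib.expected_germline_junctions(build, window=pad)
    metrics = sq.ige_metrics(calls, expected, pad=pad, sample_id=sample_id)
    return {
        "seed": seed,
        "n_iges": len(iges),
        "budget_met": met_budget,
        "insert_range": list(insert_range),
        "metrics": metrics,
        "calls": calls,
        "expected": expected,
        "build": build,
        "n_junctions": len(junctions),
    }


def run_sample_comparison(
    sim_a: cs.SimConfig, sim_b: cs.SimConfig, pad: int = 250, k: int = 21
) -> dict:
    """Two samples from one genome (e.g. two cell populations from the
    same animal): per-sample calls, the pad-flanked asymmetric
    differences, and the germline-shared set.

    Both configurations must describe the same genome (same seed-driven
    genome stage); only the amplification and sequencing seeds differ.
    """
    rngs_a = _stage_rngs(sim_a.seed, 3)
    rngs_b = _stage_rngs(sim_b.seed, 3)
    genome, loci, library = cs.simulate_genome(sim_a, rngs_a[0])

    reports = {}
    call_sets = {}
    for name, sim, rngs in (("a", sim_a, rngs_a), ("b", sim_b, rngs_b)):
        reference, fragments, _ = cs.mda_amplify(genome, sim, rngs[1])
        pairs, _ = cs.generate_reads(fragments, sim)
        mapper = Mapper(reference, k)
        aligned = mapper.map_pairs(pairs)
        calls, _ = call_sample(aligned, library, sim.read_len, sample_id=name, k=k)
        novel, _ = ic.split_reference_calls(calls, loci, pad=pad)
        call_sets[name] = novel
        reports[name] = {"n_calls": len(calls), "n_novel": len(novel)}

    a_only = ic.compare_samples(call_sets["a"], call_sets["b"], pad=pad)
    b_only = ic.compare_samples(call_sets["b"], call_sets["a"], pad=pad)
    ic.classify_germline(call_sets, pad=pad)
    shared = [c for c in call_sets["a"] if c.call_class == "germline-shared"]
    return {
        "samples": reports,
        "a_only": a_only,
        "b_only": b_only,
        "germline_shared": shared,
        "call_sets": call_sets,
    }
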