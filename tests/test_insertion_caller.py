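import numpy as np
import pytest
from scipy import stats as sps

from mobiqc import chimera_sim as cs
from mobiqc import insertion_caller as ic
from mobiqc import pipeline as pl
from mobiqc.core_io import ElementLibrary, Interval, revcomp
from mobiqc.micromap import AlignedPair, Mapper, MatePlacement


def _pair(name, c1, p1, s1, c2, p2, s2, seq1="A" * 100, seq2="A" * 100, aln=100):
    return AlignedPair(
        name, seq1, seq2,
        MatePlacement("unique", c1, p1, s1, aln_len=aln),
        MatePlacement("unique", c2, p2, s2, aln_len=aln),
    )


class TestFindDiscordant:
    @pytest.fixture
    def library(self, rng):
        return ElementLibrary([("F", cs.random_seq(600, 0.42, rng))])

    def test_element_mate_plus_anchor(self, library):
        pair = _pair("p", "chr1", 1000, "+", "chr1", 90_000, "+",
                     seq2=library.seq("F")[100:200])
        (d,) = ic.find_discordant([pair], library, (400, 600))
        assert (d.anchor_chrom, d.anchor_pos, d.element, d.side) == ("chr1", 1000, "F", "5p")

    def test_concordant_pair_not_emitted(self, library):
        pair = _pair("p", "chr1", 1000, "+", "chr1", 1400, "-",
                     seq2=library.seq("F")[100:200])
        assert ic.find_discordant([pair], library, (400, 600)) == []

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            ic.find_discordant([], ElementLibrary([]), (400, 600))

    def test_planted_copy_truth_oracle(self, rng):
        """With one planted element copy and no chimera, the discordant
        pairs are exactly those from fragments straddling the insertion."""
        sim = cs.SimConfig(seed=21, chrom_lengths=(60_000,), families=(),
                           chimera_rate=0.0, coverage=25.0)
        genome, _, _ = cs.simulate_genome(sim)
        elem = cs.random_seq(400, 0.42, np.random.default_rng(99))
        library = ElementLibrary([("E", elem)])
        site = 30_000
        sample, _ = cs.plant_insertion(genome, elem, "chr1", site, tsd_len=4,
                                       polya_len=8, element_name="E")
        _, frags, _ = cs.mda_amplify(sample, sim)
        pairs, _ = cs.generate_reads(frags, sim)
        aligned = Mapper(genome, 21).map_pairs(pairs)  # reference lacks the copy
        insert_range = ic.estimate_insert_range(aligned)
        disc = ic.find_discordant(aligned, library, insert_range)
        assert disc, "planted insertion produced no discordant evidence"
        ins_len = 400 + 8 + 4
        straddlers = {
            f"frag{f.fid}" for f in frags
            if f.start < site + ins_len and site < f.end
        }
        got = {d.read_id for d in disc}
        assert got <= straddlers
        for d in disc:
            assert d.element == "E"
            assert abs(d.anchor_pos - site) < insert_range[1] + 50


class TestClusterCalls:
    def test_nearby_anchors_merge(self):
        disc = [
            ic.DiscordantPair("r1", "c", 1000, "+", "F", "5p"),
            ic.DiscordantPair("r2", "c", 1050, "-", "F", "3p"),
        ]
        (call,) = ic.cluster_calls(disc, window=500, read_len=100)
        assert call.support_total == 2
        assert (call.support_5p, call.support_3p) == (1, 1)
        assert (call.start, call.end) == (1000, 1150)

    def test_distant_anchors_split(self):
        disc = [
            ic.DiscordantPair("r1", "c", 1000, "+", "F", "5p"),
            ic.DiscordantPair("r2", "c", 11_000, "+", "F", "5p"),
        ]
        assert len(ic.cluster_calls(disc, window=500, read_len=100)) == 2

    def test_matches_brute_force_single_linkage(self, rng):
        disc = [
            ic.DiscordantPair(
                f"r{i}", f"c{int(rng.integers(1, 3))}", int(rng.integers(0, 50_000)),
                "+", f"F{int(rng.integers(1, 4))}", "5p",
            )
            for i in range(500)
        ]
        window = 400
        calls = ic.cluster_calls(disc, window=window, read_len=100)

        # brute force: union-find over all pairs within the window
        parent = list(range(len(disc)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(disc)):
            for j in range(i + 1, len(disc)):
                a, b = disc[i], disc[j]
                if (
                    a.element == b.element
                    and a.anchor_chrom == b.anchor_chrom
                    and abs(a.anchor_pos - b.anchor_pos) <= window
                ):
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(len(disc)):
            groups.setdefault(find(i), []).append(disc[i])
        expected = sorted(
            (
                d[0].element,
                d[0].anchor_chrom,
                min(x.anchor_pos for x in d),
                max(x.anchor_pos for x in d) + 100,
                len(d),
            )
            for d in groups.values()
        )
        got = sorted((c.element, c.chrom, c.start, c.end, c.support_total) for c in calls)
        assert got == expected

    def test_min_support_filter(self):
        disc = [ic.DiscordantPair("r", "c", 10, "+", "F", "5p")]
        assert ic.cluster_calls(disc, 500, 100, min_support=2) == []


class TestPenetrance:
    def _call(self):
        return ic.InsertionCall("F", "c", 1000, 1200, 5, 5)

    def test_no_spanning_pairs(self):
        call = ic.InsertionCall("F", "c", 1000, 1200, 5, 5)
        (out,) = ic.estimate_penetrance([call], [], (400, 600))
        assert out.penetrance == 1.0 and out.reference_spanning == 0

    def test_half_spanning(self):
        call = ic.InsertionCall("F", "c", 1000, 1200, 3, 2)
        # five concordant pairs whose inner gap crosses the midpoint 1100
        pairs = [
            _pair(f"p{i}", "c", 900, "+", "c", 1300, "-")
            for i in range(5)
        ]
        (out,) = ic.estimate_penetrance([call], pairs, (400, 600))
        assert out.reference_spanning == 5
        assert out.penetrance == pytest.approx(0.5)

    def test_planted_germline_penetrance_high(self):
        """At 40x a homozygous planted insertion shows penetrance near 1
        (all fragments crossing the site carry the element)."""
        vals = []
        for seed in range(20):
            sim = cs.SimConfig(seed=100 + seed, chrom_lengths=(50_000,), families=(),
                               chimera_rate=0.0, coverage=40.0)
            genome, _, _ = cs.simulate_genome(sim)
            elem = cs.random_seq(500, 0.42, np.random.default_rng(7))
            library = ElementLibrary([("E", elem)])
            sample, _ = cs.plant_insertion(genome, elem, "chr1", 25_000,
                                           tsd_len=4, polya_len=10, element_name="E")
            _, frags, _ = cs.mda_amplify(sample, sim)
            pairs, _ = cs.generate_reads(frags, sim)
            aligned = Mapper(genome, 21).map_pairs(pairs)
            calls, _ = pl.call_sample(aligned, library, sim.read_len)
            assert calls, f"no call recovered at seed {seed}"
            best = max(calls, key=lambda c: c.support_total)
            vals.append(best.penetrance)
        assert all(0.8 <= v <= 1.0 for v in vals)


class TestCompareSamples:
    def _call(self, chrom, start, end, element="F"):
        return ic.InsertionCall(element, chrom, start, end, 1, 0)

    def test_identical_sets_empty(self):
        a = [self._call("c", 1000, 1100)]
        assert ic.compare_samples(a, list(a)) == []

    def test_pad_overlap_removes(self):
        a = [self._call("c", 1000, 1100)]
        b = [self._call("c", 1200, 1300, element="G")]  # element ignored
        assert ic.compare_samples(a, b, pad=250) == []
        assert ic.compare_samples(a, b, pad=50) == a

    def test_matches_brute_force(self, rng):
        def rand_calls(n):
            return [
                self._call(
                    f"c{int(rng.integers(1, 3))}",
                    s := int(rng.integers(0, 20_000)),
                    s + int(rng.integers(50, 300)),
                )
                for _ in range(n)
            ]

        for _ in range(10):
            a, b = rand_calls(30), rand_calls(30)
            got = ic.compare_samples(a, b, pad=250)
            expected = [
                c for c in a
                if not any(
                    c.chrom == o.chrom
                    and c.start < o.end + 250
                    and o.start - 250 < c.end
                    for o in b
                )
            ]
            assert got == expected


class TestClassifyGermline:
    def _call(self, chrom, start, element="F"):
        return ic.InsertionCall(element, chrom, start, start + 100, 1, 0)

    def test_shared_everywhere_is_germline(self):
        sets = {
            "s1": [self._call("c", 1000), self._call("c", 50_000, "G")],
            "s2": [self._call("c", 1050)],
        }
        ic.classify_germline(sets)
        assert sets["s1"][0].call_class == "germline-shared"
        assert sets["s1"][1].call_class == "sample-specific"
        assert sets["s2"][0].call_class == "germline-shared"

    def test_single_sample_all_specific(self):
        sets = {"s1": [self._call("c", 1000)]}
        ic.classify_germline(sets)
        assert sets["s1"][0].call_class == "sample-specific"


def test_artefact_count_monotone_in_chimera_rate():
    """Artefactual non-reference calls scale with the chimera rate
    (Spearman rho > 0.9 over a rate grid, 5 seeds each)."""
    rates = [0.01, 0.02, 0.04, 0.08, 0.16]
    fams = (cs.Family("E1", 500, 20), cs.Family("E2", 400, 40), cs.Family("E3", 600, 10))
    xs, ys = [], []
    for rate in rates:
        for seed in range(5):
            sim = cs.SimConfig(seed=300 + seed, chrom_lengths=(200_000,), families=fams,
                               chimera_rate=rate, coverage=15.0)
            genome, loci, library = cs.simulate_genome(sim)
            ref, frags, _ = cs.mda_amplify(genome, sim)
            pairs, _ = cs.generate_reads(frags, sim)
            aligned = Mapper(ref, 21).map_pairs(pairs)
            calls, _ = pl.call_sample(aligned, library, sim.read_len)
            novel, _ = ic.split_reference_calls(calls, loci)
            xs.append(rate)
            ys.append(len(novel))
    rho = sps.spearmanr(xs, ys).statistic
    assert rho > 0.9
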