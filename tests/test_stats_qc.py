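import numpy as np
import pandas as pd
import pytest

from mobiqc import stats_qc as sq
from mobiqc.core_io import Interval
from mobiqc.insertion_caller import InsertionCall
from mobiqc.micromap import AlignedPair, MatePlacement


def _call(element, chrom, start, end):
    return InsertionCall(element, chrom, start, end, 1, 0)


class TestIgeMetrics:
    def test_recovery_and_artefacts(self):
        expected = [Interval("c", 1000, 1501, "ige1"), Interval("c", 8000, 8501, "ige2")]
        calls = [
            _call("ige1", "c", 1100, 1200),     # recovers ige1
            _call("ige2", "c", 1100, 1200),     # wrong IGE at that junction
            _call("ige1", "c", 40_000, 40_100), # far away
        ]
        m = sq.ige_metrics(calls, expected, pad=250)
        assert (m.n_expected, m.n_recovered, m.n_artefact) == (2, 1, 2)
        assert m.sensitivity == pytest.approx(0.5)

    def test_denominator_independent_of_calls(self):
        expected = [Interval("c", 1000, 1501, "ige1")]
        assert sq.ige_metrics([], expected).n_expected == 1


class TestRegression:
    def test_proportionality_slope_one(self):
        x = {f"e{i}": v for i, v in enumerate([1, 10, 100, 1000])}
        y = {k: 2 * v for k, v in x.items()}
        fit = sq.loglog_abundance_regression(x, y)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_power_law_slope_two(self):
        x = {f"e{i}": v for i, v in enumerate([2, 5, 20, 80])}
        y = {k: v**2 for k, v in x.items()}
        assert sq.loglog_abundance_regression(x, y).slope == pytest.approx(2.0)

    def test_zero_counts_excluded_and_min_points(self):
        x = {"a": 1.0, "b": 10.0, "c": 100.0, "d": 5.0}
        y = {"a": 2.0, "b": 20.0, "c": 200.0, "d": 0.0}
        assert sq.loglog_abundance_regression(x, y).n == 3
        with pytest.raises(ValueError):
            sq.loglog_abundance_regression({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_rescaling_invariance(self, rng):
        x = {f"e{i}": float(v) for i, v in enumerate(rng.integers(1, 500, size=10))}
        y = {k: float(v * rng.uniform(0.5, 2.0)) for k, v in x.items()}
        base = sq.loglog_abundance_regression(x, y).slope
        scaled = sq.loglog_abundance_regression(
            {k: 7.3 * v for k, v in x.items()}, {k: 0.11 * v for k, v in y.items()}
        ).slope
        assert scaled == pytest.approx(base)


class TestHovering:
    loci = [Interval("c", 10_000, 11_000, "F", "+")]

    def test_downstream_distance_signed(self):
        prof = sq.hovering_profile([_call("F", "c", 13_950, 14_050)], self.loci)
        assert prof["distances"][0][2] == pytest.approx(3001, abs=1)
        assert prof["median_abs_nt"] == pytest.approx(3001, abs=1)

    def test_upstream_negative_and_inside_zero(self):
        prof = sq.hovering_profile(
            [_call("F", "c", 7_950, 8_050), _call("F", "c", 10_400, 10_500)], self.loci
        )
        assert prof["distances"][0][2] == -2000
        assert prof["distances"][1][2] == 0

    def test_unassigned_bucket(self):
        prof = sq.hovering_profile([_call("G", "c", 100, 200)], self.loci)
        assert prof["n_unassigned"] == 1 and prof["median_abs_nt"] is None


class TestElementFpkm:
    def _pair(self, chrom, pos):
        return AlignedPair(
            "p", "A", "A",
            MatePlacement("unique", chrom, pos, "+", aln_len=100),
            MatePlacement("unique", chrom, pos + 300, "-", aln_len=100),
        )

    def test_arithmetic(self):
        te = [Interval("TE", 0, 2000, "F")]
        pairs = [self._pair("TE", 50) for _ in range(10)]
        pairs += [self._pair("chr1", i) for i in range(1_000_000 - 10)]
        fpkm = sq.element_fpkm(pairs, te)
        assert fpkm["F"] == pytest.approx(5.0)

    def test_zero_fragments(self):
        te = [Interval("TE", 0, 2000, "F")]
        assert sq.element_fpkm([self._pair("chr1", 5)], te)["F"] == 0.0

    def test_copy_number_ratio(self):
        """Simulated 2x copy number at equal length gives ~2x FPKM."""
        from mobiqc import chimera_sim as cs
        from mobiqc import ige_builder as ib
        from mobiqc.micromap import Mapper

        ratios = []
        for seed in range(5):
            fams = (cs.Family("A", 500, 8), cs.Family("B", 500, 4))
            sim = cs.SimConfig(seed=700 + seed, chrom_lengths=(120_000,), families=fams,
                               chimera_rate=0.0, coverage=12.0)
            genome, loci, lib = cs.simulate_genome(sim)
            dmclean, te = ib.build_dmclean(genome, lib, loci)
            _, frags, _ = cs.mda_amplify(genome, sim)
            pairs, _ = cs.generate_reads(frags, sim)
            aligned = Mapper(dmclean, 21).map_pairs(pairs)
            fpkm = sq.element_fpkm(aligned, te)
            ratios.append(fpkm["A"] / fpkm["B"])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)


class TestDepthNormalisation:
    def test_linear_scaling(self):
        value, method, warned = sq.normalize_to_depth(1000, 36.6, 18.3)
        assert value == pytest.approx(500.0) and method == "linear" and not warned

    def test_upscaling_warned(self):
        _, _, warned = sq.normalize_to_depth(100, 10.0, 20.0)
        assert warned

    def test_subsample_deterministic(self):
        pairs = list(range(10_000))
        a = sq.subsample_pairs(pairs, 0.5, seed=9)
        b = sq.subsample_pairs(pairs, 0.5, seed=9)
        assert a == b
        assert len(a) == pytest.approx(5000, abs=200)

    def test_subsampled_artefacts_track_linear_prediction(self):
        """Halving the reads roughly halves the artefact count."""
        from mobiqc import chimera_sim as cs
        from mobiqc import insertion_caller as ic
        from mobiqc import pipeline as pl
        from mobiqc.micromap import Mapper

        rel_errs = []
        for seed in range(5):
            fams = (cs.Family("E1", 500, 20), cs.Family("E2", 400, 30))
            sim = cs.SimConfig(seed=800 + seed, chrom_lengths=(150_000,), families=fams,
                               chimera_rate=0.08, coverage=20.0)
            genome, loci, lib = cs.simulate_genome(sim)
            ref, frags, _ = cs.mda_amplify(genome, sim)
            pairs, _ = cs.generate_reads(frags, sim)
            mapper = Mapper(ref, 21)

            def artefacts(read_pairs):
                aligned = mapper.map_pairs(read_pairs)
                calls, _ = pl.call_sample(aligned, lib, sim.read_len)
                novel, _ = ic.split_reference_calls(calls, loci)
                return sum(c.support_total for c in novel)

            full = artefacts(pairs)
            half = artefacts(sq.subsample_pairs(pairs, 0.5, seed=1))
            predicted, _, _ = sq.normalize_to_depth(full, 1.0, 0.5)
            rel_errs.append(abs(half - predicted) / predicted)
        assert np.mean(rel_errs) < 0.25


class TestPoolingDilution:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((30, 1800, 2, 25), (108_000, 4320.0)),
            ((1, 1800, 2, 36), (3600, 100.0)),
            ((1, 1, 1, 1), (1, 1.0)),
        ],
    )
    def test_arithmetic(self, args, expected):
        assert sq.pooling_dilution(*args) == expected

    def test_bad_depth(self):
        with pytest.raises(ValueError):
            sq.pooling_dilution(1, 1, 1, 0)


class TestDdct:
    def _table(self, ddct_true=0.0, noise=0.0, rng=None, reps=3):
        rows = []
        for cond, shift in (("kc", ddct_true), ("brain", 0.0)):
            for rep in range(reps):
                eps = rng.normal(0, noise, size=3) if rng is not None else np.zeros(3)
                rows += [
                    {"gene": "hk1", "condition": cond, "replicate": rep, "ct": 20.0 + eps[0]},
                    {"gene": "hk2", "condition": cond, "replicate": rep, "ct": 22.0 + eps[1]},
                    {"gene": "tgt", "condition": cond, "replicate": rep, "ct": 25.0 + shift + eps[2]},
                ]
        return pd.DataFrame(rows)

    def test_null_fold_one(self):
        out = sq.ddct_fold_change(self._table(), "tgt", "kc", "brain", ["hk1", "hk2"])
        assert out["fold"] == pytest.approx(1.0)

    def test_ten_cycles_is_1024_fold(self):
        out = sq.ddct_fold_change(self._table(ddct_true=-10.0), "tgt", "kc", "brain", ["hk1", "hk2"])
        assert out["fold"] == pytest.approx(1024.0)

    def test_swap_inverts_fold(self, rng):
        t = self._table(ddct_true=-2.0, noise=0.3, rng=rng)
        ab = sq.ddct_fold_change(t, "tgt", "kc", "brain", ["hk1", "hk2"])
        ba = sq.ddct_fold_change(t, "tgt", "brain", "kc", ["hk1", "hk2"])
        assert ab["fold"] * ba["fold"] == pytest.approx(1.0)

    def test_missing_housekeeping_errors(self):
        with pytest.raises(ValueError):
            sq.ddct_fold_change(self._table(), "tgt", "kc", "brain", ["nope"])

    def test_bounds_calibration(self, rng):
        """One-SEM bounds cover the true fold at roughly the 1-sigma
        rate for a difference of normal means (~68%, not more)."""
        hits = 0
        trials = 300
        for _ in range(trials):
            t = self._table(ddct_true=-1.5, noise=0.4, rng=rng, reps=4)
            out = sq.ddct_fold_change(t, "tgt", "kc", "brain", ["hk1", "hk2"])
            if out["lower"] <= 2**1.5 <= out["upper"]:
                hits += 1
        assert 0.5 < hits / trials < 0.85
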