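import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from b2proc import metagene as mg
from b2proc import processing_ratio as pr
from b2proc import simulate_sample
from b2proc.core import GenomicInterval, SampleManifest, SampleEntry

from conftest import make_locus, make_read


def _events(positions):
    return [mg.FivePrimeEvent("l", int(p)) for p in positions]


class TestFragmentWindow:
    def test_inclusive_bounds(self):
        assert pr.count_fragment_window(_events([94, 95, 110, 111])) == 2

    def test_empty(self):
        assert pr.count_fragment_window([]) == 0

    def test_matches_linear_scan_oracle(self, rng):
        pos = rng.integers(1, 121, size=1000)
        got = pr.count_fragment_window(_events(pos))
        assert got == int(((pos >= 95) & (pos <= 110)).sum())

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            pr.count_fragment_window([], lo=10, hi=5)


class TestTrnaCounting:
    def _trna(self, start=1000, length=72, strand="+", chrom="chr1"):
        return GenomicInterval(chrom, start, start + length, strand)

    def test_read_at_trna_start_counted(self):
        t = self._trna()
        read = make_read(start=1000, end=1060)
        assert pr.count_trna_short_reads([read], [t]) == 1

    def test_offset_sixteen_not_counted(self):
        t = self._trna()
        assert pr.count_trna_short_reads([make_read(start=1016, end=1076)], [t]) == 0
        assert pr.count_trna_short_reads([make_read(start=1015, end=1075)], [t]) == 1

    def test_upstream_window_edge(self):
        t = self._trna()
        assert pr.count_trna_short_reads([make_read(start=995, end=1055)], [t]) == 1
        assert pr.count_trna_short_reads([make_read(start=994, end=1054)], [t]) == 0

    def test_minus_strand_trna_uses_its_own_orientation(self):
        t = self._trna(strand="-")  # start of tRNA = genomic end-1 = 1071
        read = make_read(start=1012, end=1072, strand="-")  # 5' base 1071, offset 0
        assert pr.count_trna_short_reads([read], [t]) == 1
        far = make_read(start=996, end=1056, strand="-")  # 5' 1055, offset 16
        assert pr.count_trna_short_reads([far], [t]) == 0

    def test_one_count_per_read_and_oracle(self, rng):
        trnas = [self._trna(start=s) for s in (1000, 1010, 5000)]
        reads = []
        for i in range(50):
            start = int(rng.integers(900, 5200))
            reads.append(make_read(start=start, end=start + 40, read_id=f"r{i}"))
        got = pr.count_trna_short_reads(reads, trnas)
        expected = 0
        for read in reads:
            g5 = read.five_prime
            expected += any(t.start - 5 <= g5 <= t.start + 15 for t in trnas)
        assert got == expected


class TestLongCounting:
    def test_read_spanning_two_loci_counts_once(self):
        a = make_locus(start=100, end=288)
        b = make_locus(start=400, end=588)
        read = make_read(start=50, end=700, library="long")
        assert pr.count_long_full_length([read], [a, b]) == 1

    def test_abutting_read_not_counted(self):
        a = make_locus(start=100, end=288)
        read = make_read(start=288, end=500, library="long")
        assert pr.count_long_full_length([read], [a]) == 0

    def test_matches_all_pairs_oracle(self, rng):
        loci = [make_locus(start=int(s), end=int(s) + 188) for s in range(500, 20000, 1500)]
        reads = []
        for i in range(200):
            start = int(rng.integers(0, 21000))
            reads.append(
                make_read(start=start, end=start + int(rng.integers(100, 900)),
                          read_id=f"r{i}", library="long")
            )
        got = pr.count_long_full_length(reads, loci)
        expected = sum(
            any(r.interval.overlaps(l.interval) for l in loci) for r in reads
        )
        assert got == expected


class TestComputeRatio:
    def test_hand_arithmetic_literal(self):
        c = pr.ProcessingCounts(F=100, T=1000, Ns=10**6, B=500, Nl=10**7)
        res = pr.compute_ratio(c)
        assert res.ratio == pytest.approx(2.0e9)
        assert res.mode == "literal"

    def test_zero_fragments_zero_ratio(self):
        c = pr.ProcessingCounts(F=0, T=10, Ns=100, B=10, Nl=100)
        assert pr.compute_ratio(c).ratio == 0
        assert pr.compute_ratio(c, mode="trna_relative").ratio == 0

    def test_doubling_b_halves_ratio(self):
        base = pr.ProcessingCounts(F=50, T=100, Ns=1000, B=20, Nl=1000)
        double = pr.ProcessingCounts(F=50, T=100, Ns=1000, B=40, Nl=1000)
        assert pr.compute_ratio(double).ratio == pytest.approx(
            pr.compute_ratio(base).ratio / 2
        )

    def test_zero_normalizer_names_failing_count(self):
        with pytest.raises(pr.InsufficientNormalizerError, match="T"):
            pr.compute_ratio(pr.ProcessingCounts(F=1, T=0, Ns=10, B=5, Nl=10))
        with pytest.raises(pr.InsufficientNormalizerError, match="B"):
            pr.compute_ratio(pr.ProcessingCounts(F=1, T=5, Ns=10, B=0, Nl=10))

    counts_st = st.builds(
        pr.ProcessingCounts,
        F=st.integers(0, 10**5),
        T=st.integers(1, 10**5),
        Ns=st.integers(10**5, 10**7),
        B=st.integers(1, 10**5),
        Nl=st.integers(1, 10**7),
    )

    @given(counts=counts_st)
    @settings(max_examples=100, deadline=None)
    def test_mode_relation_literal_is_trna_relative_times_ns(self, counts):
        lit = pr.compute_ratio(counts, "literal").ratio
        rel = pr.compute_ratio(counts, "trna_relative").ratio
        assert lit == pytest.approx(rel * counts.Ns, rel=1e-12)

    @given(counts=counts_st, c=st.integers(2, 50))
    @settings(max_examples=50, deadline=None)
    def test_depth_scaling_behaviour(self, counts, c):
        """Literal mode scales with short depth; trna_relative is invariant
        to joint scaling of F and T."""
        scaled = pr.ProcessingCounts(counts.F * c, counts.T * c, counts.Ns * c,
                                     counts.B, counts.Nl)
        lit0 = pr.compute_ratio(counts, "literal").ratio
        lit1 = pr.compute_ratio(scaled, "literal").ratio
        assert lit1 == pytest.approx(lit0 * c, rel=1e-12)
        rel0 = pr.compute_ratio(counts, "trna_relative").ratio
        joint = pr.ProcessingCounts(counts.F * c, counts.T * c, counts.Ns,
                                    counts.B, counts.Nl)
        assert pr.compute_ratio(joint, "trna_relative").ratio == pytest.approx(
            rel0, rel=1e-12
        )

    @given(counts=counts_st)
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_in_counts(self, counts):
        for mode in ("literal", "trna_relative"):
            base = pr.compute_ratio(counts, mode).ratio
            up_f = pr.ProcessingCounts(counts.F + 1, counts.T, counts.Ns, counts.B, counts.Nl)
            up_t = pr.ProcessingCounts(counts.F, counts.T + 1, counts.Ns, counts.B, counts.Nl)
            up_b = pr.ProcessingCounts(counts.F, counts.T, counts.Ns, counts.B + 1, counts.Nl)
            assert pr.compute_ratio(up_f, mode).ratio > base
            if counts.F > 0:
                assert pr.compute_ratio(up_t, mode).ratio < base
                assert pr.compute_ratio(up_b, mode).ratio < base


class TestComputeSample:
    def test_pipeline_equals_composition_of_parts(self, genome, tmp_path):
        from b2proc import synthetic_data as sd

        sim = simulate_sample(genome, 0.2, sample_id="X", seed=5)
        counts = pr.compute_sample_counts(
            sim.short, sim.long, genome.loci, genome.trna_loci,
            Ns=sim.truth["Ns"], Nl=sim.truth["Nl"],
        )
        assert (counts.F, counts.T, counts.B) == (
            sim.truth["F"], sim.truth["T"], sim.truth["B"]
        )
        # file-based route gives the identical result
        short_p, long_p = tmp_path / "x.short.sam", tmp_path / "x.long.sam"
        sd.write_sam(sim.short, genome, short_p)
        sd.write_sam(sim.long, genome, long_p)
        entry = SampleEntry("X", "G", str(short_p), str(long_p),
                            sim.truth["Ns"], sim.truth["Nl"])
        res = pr.compute_sample(entry, genome.loci, genome.trna_loci)
        assert res.counts == counts
        assert res.ratio == pr.compute_ratio(counts).ratio
        # determinism: two technical copies of the same input
        res2 = pr.compute_sample(entry, genome.loci, genome.trna_loci)
        assert res2 == res

    def test_zero_trna_reads_raise_insufficient_normalizer(self, genome):
        sim = simulate_sample(genome, 0.2, n_trna_reads=0, sample_id="X", seed=5)
        counts = pr.compute_sample_counts(
            sim.short, sim.long, genome.loci, genome.trna_loci,
            Ns=sim.truth["Ns"], Nl=sim.truth["Nl"],
        )
        with pytest.raises(pr.InsufficientNormalizerError):
            pr.compute_ratio(counts)


def _manifest(groups):
    entries = []
    for g, ids in groups.items():
        for i in ids:
            entries.append(SampleEntry(i, g, short_library_size=1, long_library_size=1))
    return SampleManifest(entries)


def _results(values):
    c = pr.ProcessingCounts(F=1, T=1, Ns=1, B=1, Nl=1)
    return [pr.ProcessingRatioResult(sid, c, v, "literal") for sid, v in values.items()]


class TestCompareGroups:
    def test_toy_numbers_match_textbook_t(self):
        manifest = _manifest({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]})
        res = _results({"a1": 1, "a2": 2, "a3": 3, "b1": 4, "b2": 5, "b3": 6})
        comp = pr.compare_groups(res, manifest)
        assert comp.t == pytest.approx(-3.674, abs=1e-3)
        assert comp.p == pytest.approx(0.0213, abs=1e-4)
        assert comp.df == 4

    def test_identical_groups(self):
        manifest = _manifest({"A": ["a1", "a2"], "B": ["b1", "b2"]})
        res = _results({"a1": 2.0, "a2": 3.0, "b1": 2.0, "b2": 3.0})
        comp = pr.compare_groups(res, manifest)
        assert comp.t == 0 and comp.p == pytest.approx(1.0)

    def test_directional_test_halves_p_on_stated_side(self):
        manifest = _manifest({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]})
        res = _results({"a1": 4, "a2": 5, "a3": 6, "b1": 1, "b2": 2, "b3": 3})
        two = pr.compare_groups(res, manifest, sided="two")
        greater = pr.compare_groups(res, manifest, sided="greater",
                                    group_order=("A", "B"))
        assert greater.p == pytest.approx(two.p / 2)

    def test_small_groups_rejected(self):
        manifest = _manifest({"A": ["a1"], "B": ["b1", "b2"]})
        res = _results({"a1": 1, "b1": 2, "b2": 3})
        with pytest.raises(ValueError, match="n >= 2"):
            pr.compare_groups(res, manifest)

    def test_welch_reports_noninteger_df(self):
        manifest = _manifest({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3", "b4"]})
        res = _results({"a1": 1, "a2": 2, "a3": 3, "b1": 10, "b2": 30, "b3": 50, "b4": 70})
        comp = pr.compare_groups(res, manifest, variance="welch")
        assert comp.variance == "welch"
        assert comp.df != int(comp.df) or comp.df < 5
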