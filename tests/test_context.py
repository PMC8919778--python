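"""5'-end profile scanning, terminator shape and distances."""

import math

import numpy as np
import pytest

from g2i.assembly import IntronCall
from g2i.context import (
    FivePrimeProfile,
    bin_distance,
    build_profile,
    classify_terminator_shape,
    locate_5prime,
    scan_profile,
    score_window,
    terminator_distance,
)
from g2i.io import GenomeRecord, TerminatorRecord, revcomp

from conftest import mk_hit


def uniform_profile(per_column: float, length: int = 10) -> FivePrimeProfile:
    m = np.full((length, 4), -5.0)
    m[:, 0] = per_column  # base A scores per_column, others -5
    return FivePrimeProfile(iep_type="C", logodds=m)


def make_call(rt_start, rt_end, strand="+", iep_type="C"):
    return IntronCall(
        replicon_id="chr1",
        strand=strand,
        category="iep_containing",
        span=(rt_start, rt_end),
        rt_hit=mk_hit(kind="RT", start=rt_start, end=rt_end, strand=strand),
        iep_type=iep_type,
    )


class TestBuildProfile:
    def test_degenerate_alignment_scores_itself_highest(self):
        aln = ["GTGCGATT"] * 5
        prof = build_profile(aln, "C", pseudocount=0.1)
        # each matched column: log2((5.1/5.4)/0.25)
        expected = 8 * math.log2((5.1 / 5.4) / 0.25)
        assert score_window(prof, "GTGCGATT") == pytest.approx(expected)
        assert score_window(prof, "GTGCGATT") > score_window(prof, "GTGCGATA")

    def test_half_half_column_closed_form(self):
        prof = build_profile(["AACGTACG", "CACGTACG"], "C", pseudocount=0.1)
        # counts A: 1.1 of 2.4 total -> log2(1.1/2.4/0.25)
        assert prof.logodds[0, 0] == pytest.approx(math.log2(1.1 / 2.4 / 0.25))
        assert prof.logodds[0, 2] == pytest.approx(math.log2(0.1 / 2.4 / 0.25))

    def test_all_gap_column_dropped(self):
        prof = build_profile(["A-ACGTACG", "A-ACGTACG"], "C")
        assert len(prof) == 8

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            build_profile([], "C")


class TestLocate5Prime:
    def test_bit_threshold_boundary(self):
        g = GenomeRecord("chr1", "A" * 3000, topology="linear")
        call = make_call(2000, 2600)
        below = {"C": uniform_profile(0.99)}  # best window 9.9 bits
        at = {"C": uniform_profile(1.00)}  # 10.0 bits
        assert locate_5prime(call, g, below, iep_start=2000) is None
        assert locate_5prime(call, g, at, iep_start=2000) is not None

    def test_highest_scoring_site_wins(self, parts):
        profiles = parts.profiles()
        cons = parts.five_prime_consensus["C"]
        rng = np.random.default_rng(3)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        # plant exact consensus at 1500 and a weaker (mutated) copy at 1800
        weak = cons[:6] + revcomp(cons[6:12]) + cons[12:]
        seq = bg[:1500] + cons + bg[1536:1800] + weak + bg[1836:]
        g = GenomeRecord("chr1", seq, topology="linear")
        call = make_call(2400, 3000)
        assert locate_5prime(call, g, profiles, iep_start=2400) == 1500

    def test_minus_strand_mirrored(self, parts):
        profiles = parts.profiles()
        cons = parts.five_prime_consensus["C"]
        rng = np.random.default_rng(4)
        bg = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        seq = bg[:1500] + revcomp(cons) + bg[1536:]
        g = GenomeRecord("chr1", seq, topology="linear")
        call = make_call(400, 1000, strand="-")
        # 5' base of the match on '-' is its highest coordinate
        assert locate_5prime(call, g, profiles, iep_start=999) == 1535

    def test_g1_type_always_none(self, parts):
        g = GenomeRecord("chr1", "A" * 2000, topology="linear")
        call = make_call(1500, 1900, iep_type="G_g1")
        assert locate_5prime(call, g, parts.profiles(), iep_start=1500) is None


class TestTerminatorShape:
    def genome_with_tail(self, tail):
        seq = "G" * 100 + tail + "G" * 50
        return GenomeRecord("chr1", seq, topology="linear")

    @pytest.mark.parametrize(
        "tail,shape",
        [
            ("TTTTAGGCAA", "L"),
            ("TTAGCCAGCA", "I"),
            ("TTTAAAGGGC", "I"),  # 3 T
            ("TATATAGGGT", "L"),  # exactly 4 scattered T
        ],
    )
    def test_tail_rule(self, tail, shape):
        g = self.genome_with_tail(tail)
        term = TerminatorRecord("chr1", "+", stem_start=70, stem_end=99, term_3prime=105)
        assert classify_terminator_shape(term, g) == shape

    def test_minus_strand_reads_reverse_complement(self):
        # tail upstream of the stem on the forward axis, revcomp has 4 T
        seq = "G" * 40 + "AAAAGGGGGG" + "C" * 50
        g = GenomeRecord("chr1", seq, topology="linear")
        term = TerminatorRecord("chr1", "-", stem_start=50, stem_end=80, term_3prime=45)
        assert classify_terminator_shape(term, g) == "L"


class TestTerminatorDistance:
    def test_plus_strand_arithmetic(self):
        term = TerminatorRecord("chr1", "+", 900, 950, 1000)
        d, t = terminator_distance(1005, "+", [term])
        assert d == 5 and t is term

    def test_out_of_range_none(self):
        term = TerminatorRecord("chr1", "+", 900, 950, 1000)
        assert terminator_distance(7001, "+", [term], max_search=5000) is None

    def test_minus_strand_mirrored(self):
        term = TerminatorRecord("chr1", "-", 2010, 2050, 2000)
        d, _ = terminator_distance(1990, "-", [term])
        assert d == 10

    def test_downstream_terminator_never_matched(self):
        term = TerminatorRecord("chr1", "+", 1900, 1950, 2000)
        assert terminator_distance(1500, "+", [term]) is None

    def test_nearest_same_strand_wins(self):
        near = TerminatorRecord("chr1", "+", 900, 950, 1000)
        far = TerminatorRecord("chr1", "+", 400, 450, 500)
        wrong = TerminatorRecord("chr1", "-", 990, 1020, 980)
        d, t = terminator_distance(1100, "+", [far, wrong, near])
        assert d == 100 and t is near


def test_distance_bins_conserve_counts():
    distances = list(range(0, 2500, 37))
    labels = [bin_distance(d) for d in distances]
    assert len(labels) == len(distances)
    assert bin_distance(0) == "0-100" and bin_distance(100) == "0-100"
    assert bin_distance(101) == "101-200"
    assert bin_distance(1000) == "901-1000" and bin_distance(1001) == ">1000"
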