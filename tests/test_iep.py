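"""IEP region extraction, ORF finding, status classification, clustering."""

import numpy as np
import pytest

from g2i.assembly import IntronCall
from g2i.iep import (
    MotifSet,
    classify_iep,
    detect_interrupted,
    extract_iep_region,
    find_orf,
    greedy_cluster,
    IEPRecord,
    locate_iep,
    motif_completeness,
    pairwise_identity,
    strip_stops,
)
from g2i.io import GenomeRecord, revcomp
from g2i.synth import reverse_translate

from conftest import mk_hit

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_pep(rng, n):
    return "".join(AA[i] for i in rng.integers(0, 20, n))


def make_call(rt_start, rt_end, dv_start, dv_end, strand="+"):
    return IntronCall(
        replicon_id="chr1",
        strand=strand,
        category="iep_containing",
        span=(min(rt_start, dv_start), max(rt_end, dv_end)),
        rt_hit=mk_hit(kind="RT", start=rt_start, end=rt_end, strand=strand),
        dvvi_hit=mk_hit(kind="DV_VI", start=dv_start, end=dv_end, strand=strand),
        iep_type="C",
    )


class TestExtractRegion:
    def genome(self, n=10_000, topology="linear"):
        rng = np.random.default_rng(42)
        return GenomeRecord("chr1", "".join("ACGT"[i] for i in rng.integers(0, 4, n)), topology)

    def test_plus_strand_window(self):
        g = self.genome()
        region, rt_off = extract_iep_region(make_call(5000, 5600, 6900, 7000), g)
        assert region == g.sequence[4000:7200]
        assert rt_off == 1000

    def test_clamped_at_linear_start(self):
        g = self.genome()
        region, rt_off = extract_iep_region(make_call(400, 1000, 2000, 2100), g)
        assert region == g.sequence[0:2300]
        assert rt_off == 400

    def test_minus_strand_is_reverse_complemented(self):
        g = self.genome()
        region, rt_off = extract_iep_region(make_call(6900, 7500, 5000, 5100, strand="-"), g)
        assert region == revcomp(g.sequence[4800:8500])
        assert rt_off == 1000

    def test_circular_wraps_origin(self):
        g = self.genome(topology="circular")
        region, _ = extract_iep_region(make_call(500, 1100, 2000, 2100), g)
        assert region == g.sequence[-500:] + g.sequence[:2300]


class TestFindOrf:
    def test_unique_orf_recovered(self, rng):
        pep = rand_pep(rng, 450)
        orf = "ATG" + reverse_translate(pep, rng) + "TAA"
        region = "CCCC" + orf + "CCCC"
        nt0, nt1, aa = find_orf(region, (300, 900))
        assert region[nt0:nt1] == orf
        assert aa == "M" + pep

    def test_longest_of_two_orfs_wins(self, rng):
        long_pep, short_pep = rand_pep(rng, 450), rand_pep(rng, 300)
        long_orf = "ATG" + reverse_translate(long_pep, rng) + "TAA"
        short_orf = "ATG" + reverse_translate(short_pep, rng) + "TAA"
        region = "C" + short_orf + "CC" + long_orf + "C"  # different frames
        rt = (len(region) // 2 - 300, len(region) // 2 + 300)
        nt0, nt1, aa = find_orf(region, rt)
        assert aa.endswith(long_pep[-50:]) and (nt1 - nt0) >= len(long_orf)

    def test_no_orf_over_rt_errors(self):
        with pytest.raises(ValueError):
            find_orf("TAATAATAA" * 30, (0, 30))

    def test_orf_length_divisible_by_three(self, rng):
        pep = rand_pep(rng, 100)
        region = "AC" + "ATG" + reverse_translate(pep, rng) + "TAA" + "G"
        nt0, nt1, _ = find_orf(region, (2, 290))
        assert (nt1 - nt0) % 3 == 0


class TestInterrupted:
    def test_planted_internal_stop_found(self, rng):
        pep = rand_pep(rng, 200)
        nt = reverse_translate(pep, rng)
        nt = nt[: 3 * 60] + "TAA" + nt[3 * 61 :]  # replace codon 60
        region = "CC" + nt + "AA"
        stops = detect_interrupted(region, (2, 2 + len(nt)), 2)
        assert stops == [60]

    def test_terminal_stop_not_internal(self, rng):
        pep = rand_pep(rng, 100)
        nt = reverse_translate(pep, rng) + "TAA"
        assert detect_interrupted(nt, (0, len(nt)), 0) == []

    def test_no_stop_anywhere(self, rng):
        nt = reverse_translate(rand_pep(rng, 100), rng)
        assert detect_interrupted(nt, (0, len(nt)), 0) == []


class TestMotifsAndStatus:
    def motifset(self, rng):
        motifs = [rand_pep(rng, int(rng.integers(10, 51))) for _ in range(15)]
        return MotifSet(iep_type="C", motifs=motifs)

    def test_all_motifs_present(self, rng):
        ms = self.motifset(rng)
        pep = "XX".join(ms.motifs)
        presence, missing = motif_completeness(pep, ms)
        assert all(presence) and missing == 0

    @pytest.mark.parametrize("n_del,expect", [(5, "short_orf"), (4, "canonical")])
    def test_missing_motif_threshold(self, rng, n_del, expect):
        ms = self.motifset(rng)
        pep = "XX".join(ms.motifs[n_del:])
        _, missing = motif_completeness(pep, ms)
        assert missing == n_del
        rec = IEPRecord(call_ref="c", region="", n_missing_motifs=missing)
        assert classify_iep(rec) == expect

    def test_interrupted_takes_precedence(self):
        rec = IEPRecord(call_ref="c", region="", n_missing_motifs=6, internal_stop_positions=[10])
        assert classify_iep(rec) == "interrupted"

    def test_strip_stops_shrinks_by_count(self):
        assert strip_stops("AB*CD*E") == "ABCDE"


class TestLocateIEP:
    def test_exact_reference_recovered(self, rng):
        pep = rand_pep(rng, 300)
        region = "ACGT" * 30 + reverse_translate(pep, rng) + "ACGT" * 30
        aa, frame, qid, span = locate_iep(region, {"ref": pep})
        assert aa == pep and qid == "ref"
        assert span == (120, 120 + 900)

    def test_highest_scoring_reference_wins(self, rng):
        pep = rand_pep(rng, 300)
        other = rand_pep(rng, 300)
        region = reverse_translate(pep, rng)
        aa, _, qid, _ = locate_iep(region, {"good": pep, "bad": other})
        assert qid == "good"

    def test_random_region_gives_none(self, rng):
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
        assert locate_iep(region, {"ref": rand_pep(rng, 300)}) is None


class TestClustering:
    def test_identical_sequences_one_cluster(self, rng):
        s = rand_pep(rng, 120)
        (cl,) = greedy_cluster({"a": s, "b": s})
        assert sorted(cl.members) == ["a", "b"] and cl.representative in ("a", "b")

    def test_distant_sequences_two_clusters(self, rng):
        cls = greedy_cluster({"a": rand_pep(rng, 120), "b": rand_pep(rng, 120)})
        assert len(cls) == 2

    def test_chain_splits_at_representative(self, rng):
        a = rand_pep(rng, 100)
        b = list(a[:98])
        for i in rng.choice(98, size=8, replace=False):
            b[i] = AA[(AA.index(b[i]) + 1) % 20]
        b = "".join(b)
        c = list(b[:96])
        remaining = [i for i in range(96) if b[i] == a[i]]
        for i in rng.choice(remaining, size=14, replace=False):
            c[i] = AA[(AA.index(c[i]) + 3) % 20]
        c = "".join(c)
        assert pairwise_identity(a, b) >= 0.85
        assert pairwise_identity(b, c) >= 0.85
        assert pairwise_identity(a, c) < 0.85
        cls = greedy_cluster({"a": a, "b": b, "c": c})
        parts = sorted(sorted(cl.members) for cl in cls)
        assert parts == [["a", "b"], ["c"]]

    def test_partition_and_identity_floor(self, rng):
        seqs = {}
        for fam in range(8):
            root = rand_pep(rng, int(rng.integers(120, 260)))
            for m in range(int(rng.integers(2, 5))):
                s = list(root)
                for i in rng.choice(len(s), size=int(0.05 * len(s)), replace=False):
                    s[i] = AA[int(rng.integers(20))]
                seqs[f"f{fam}m{m}"] = "".join(s)
        cls = greedy_cluster(seqs)
        members = [m for cl in cls for m in cl.members]
        assert sorted(members) == sorted(seqs)  # disjoint and covering
        for cl in cls:
            for m in cl.members:
                assert pairwise_identity(seqs[m], seqs[cl.representative]) >= 0.85

    def test_deterministic_given_ids(self, rng):
        seqs = {f"s{i}": rand_pep(rng, 100) for i in range(6)}
        a = greedy_cluster(dict(sorted(seqs.items())))
        b = greedy_cluster(dict(sorted(seqs.items(), reverse=True)))
        assert [sorted(c.members) for c in a] == [sorted(c.members) for c in b]
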