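"""Gap arithmetic and intron-call assembly."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g2i.assembly import (
    AssemblyConfig,
    attach_orfless,
    call_introns,
    gap_nt,
    merge_dvvi_hits,
    pair_rt_with_dvvi,
)
from g2i.io import GenomeRecord

from conftest import mk_hit


class TestGapNt:
    def test_simple_linear_gap(self):
        assert gap_nt((100, 200), (300, 400)) == 100

    def test_overlap_clamps_to_zero(self):
        assert gap_nt((100, 300), (250, 400)) == 0

    def test_circular_wrap(self):
        assert gap_nt((900, 950), (10, 60), topology="circular", length=1000) == 60

    def test_order_violation_returns_none(self):
        assert gap_nt((300, 400), (100, 200)) is None
        assert gap_nt((300, 400), (100, 200), require_order=False) == 100

    def test_minus_strand_mirrors(self):
        # upstream on '-' means higher coordinates
        assert gap_nt((300, 400), (100, 200), strand="-") == 100
        assert gap_nt((100, 200), (300, 400), strand="-") is None

    def test_circular_unordered_takes_smaller_arc(self):
        g = gap_nt((0, 50), (900, 950), topology="circular", length=1000, require_order=False)
        assert g == 50  # back arc 950->1000->0 is shorter than forward 50->900


class TestPairing:
    def test_gap_boundary_1300(self, hit_factory):
        rt = mk_hit(kind="RT", start=2600, end=3200, iep_type="C")
        dv_ok = mk_hit(kind="DV_VI", start=4500, end=4590)
        dv_far = mk_hit(kind="DV_VI", start=4501, end=4591)
        calls, _ = pair_rt_with_dvvi([rt], [dv_ok])
        assert len(calls) == 1 and calls[0].iep_type == "C"
        calls, unpaired = pair_rt_with_dvvi([rt], [dv_far])
        assert calls == [] and unpaired == [dv_far]

    def test_strand_mismatch_blocks_pairing(self):
        rt = mk_hit(kind="RT", start=1000, end=1600, strand="-")
        dv = mk_hit(kind="DV_VI", start=2000, end=2090, strand="+")
        calls, _ = pair_rt_with_dvvi([rt], [dv])
        assert calls == []

    def test_greedy_prefers_smaller_gap_then_bits(self):
        rt_near = mk_hit(kind="RT", start=1000, end=1600, bits=100, qid="near", iep_type="C")
        rt_far = mk_hit(kind="RT", start=200, end=800, bits=200, qid="far", iep_type="E")
        dv = mk_hit(kind="DV_VI", start=1700, end=1790)
        calls, _ = pair_rt_with_dvvi([rt_near, rt_far], [dv])
        assert calls[0].rt_hit.query_id == "near"
        # equal gaps: higher bit score wins
        rt_a = mk_hit(kind="RT", start=1000, end=1600, bits=100, qid="a")
        rt_b = mk_hit(kind="RT", start=1100, end=1600, bits=150, qid="b")
        calls, _ = pair_rt_with_dvvi([rt_a, rt_b], [dv])
        assert calls[0].rt_hit.query_id == "b"

    def test_each_hit_used_at_most_once(self):
        rts = [mk_hit(kind="RT", start=s, end=s + 600, qid=f"rt{s}") for s in (0, 2000)]
        dvs = [mk_hit(kind="DV_VI", start=s, end=s + 90, qid=f"dv{s}") for s in (700, 2700)]
        calls, unpaired = pair_rt_with_dvvi(rts, dvs)
        assert len(calls) == 2 and unpaired == []
        used_rt = {c.rt_hit.query_id for c in calls}
        used_dv = {c.dvvi_hit.query_id for c in calls}
        assert len(used_rt) == 2 and len(used_dv) == 2


class TestOrfless:
    def test_d1_at_gap_boundary(self):
        dv = mk_hit(kind="DV_VI", start=4500, end=4590)
        d1_ok = mk_hit(kind="D1", start=3100, end=3200)  # gap 1300
        d1_far = mk_hit(kind="D1", start=3099, end=3199)  # gap 1301
        assert len(attach_orfless([dv], [d1_ok])) == 1
        assert attach_orfless([dv], [d1_far]) == []

    def test_paired_dvvi_excluded(self):
        rt = mk_hit(kind="RT", start=3000, end=3600)
        dv = mk_hit(kind="DV_VI", start=4000, end=4090)
        d1 = mk_hit(kind="D1", start=3500, end=3700)
        calls, unpaired = pair_rt_with_dvvi([rt], [dv])
        assert len(calls) == 1
        assert attach_orfless(unpaired, [d1]) == []

    def test_opposite_strand_d1_ignored(self):
        dv = mk_hit(kind="DV_VI", start=4500, end=4590)
        d1 = mk_hit(kind="D1", start=4000, end=4100, strand="-")
        assert attach_orfless([dv], [d1]) == []


class TestCallIntrons:
    def genome(self, n=100_000):
        return GenomeRecord("chr1", "A" * n, topology="linear")

    def test_overlapping_dvvi_merged_by_bits(self):
        dvs = [
            mk_hit(kind="DV_VI", start=1000, end=1090, bits=40.0, qid="hi"),
            mk_hit(kind="DV_VI", start=1010, end=1100, bits=30.0, qid="lo"),
        ]
        merged = merge_dvvi_hits(dvs)
        assert [h.query_id for h in merged] == ["hi"]
        rt = mk_hit(kind="RT", start=0, end=600)
        calls = call_introns(self.genome(), [rt] + dvs)
        assert len(calls) == 1 and calls[0].dvvi_hit.query_id == "hi"

    def test_empty_in_empty_out(self):
        assert call_introns(self.genome(), []) == []

    def test_span_is_hull_and_sorted(self):
        hits = [
            mk_hit(kind="RT", start=5000, end=5600),
            mk_hit(kind="DV_VI", start=6000, end=6090),
            mk_hit(kind="DV_VI", start=1000, end=1090),
            mk_hit(kind="D1", start=500, end=650),
        ]
        calls = call_introns(self.genome(), hits)
        assert [c.span for c in calls] == [(500, 1090), (5000, 6090)]
        assert [c.category for c in calls] == ["orf_less", "iep_containing"]

    def test_conservation_no_hit_in_two_calls(self):
        hits = []
        for s in (0, 3000, 6000):
            hits.append(mk_hit(kind="RT", start=s, end=s + 600, qid=f"rt{s}"))
            hits.append(mk_hit(kind="DV_VI", start=s + 900, end=s + 990, qid=f"dv{s}"))
        calls = call_introns(self.genome(), hits)
        members = [c.rt_hit.query_id for c in calls] + [c.dvvi_hit.query_id for c in calls]
        assert len(members) == len(set(members)) == 6

    @given(gap=st.integers(min_value=0, max_value=2600))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_max_gap(self, gap):
        rt = mk_hit(kind="RT", start=1000, end=1600)
        dv = mk_hit(kind="DV_VI", start=1600 + gap, end=1690 + gap)
        n_small = len(call_introns(self.genome(), [rt, dv], AssemblyConfig(max_gap=1000)))
        n_default = len(call_introns(self.genome(), [rt, dv], AssemblyConfig(max_gap=1300)))
        n_large = len(call_introns(self.genome(), [rt, dv], AssemblyConfig(max_gap=2000)))
        assert n_small <= n_default <= n_large

    def test_strand_mirror(self, parts):
        from g2i import synth
        from g2i.io import revcomp

        g = synth.generate_genome(40_000, seed=9)
        specs = [
            synth.PlantSpec("iep_intron", 5_000, "+", iep_type="C"),
            synth.PlantSpec("orfless_intron", 20_000, "-"),
        ]
        g2, truth = synth.plant(g, specs, parts, seed=2)
        hits = truth.to_domain_hits()
        calls_f = call_introns(g2, hits)
        L = g2.length
        mirrored = []
        for h in hits:
            import dataclasses

            mirrored.append(
                dataclasses.replace(
                    h, start=L - h.end, end=L - h.start, strand="-" if h.strand == "+" else "+"
                )
            )
        g_rc = GenomeRecord(g2.replicon_id, revcomp(g2.sequence))
        calls_r = call_introns(g_rc, mirrored)
        assert len(calls_f) == len(calls_r) == 2
        got = sorted((L - c.span[1], L - c.span[0], c.category, c.iep_type) for c in calls_r)
        want = sorted((c.span[0], c.span[1], c.category, c.iep_type) for c in calls_f)
        assert got == want


class TestGreedyVsBruteForce:
    """On conflict-limited instances greedy pairing equals the optimal matching."""

    def brute_force(self, rts, dvs, cfg=AssemblyConfig()):
        best = None
        n = min(len(rts), len(dvs))
        for k in range(n, -1, -1):
            for rsub in itertools.permutations(range(len(rts)), k):
                for dsub in itertools.combinations(range(len(dvs)), k):
                    total = 0
                    ok = True
                    for i, j in zip(rsub, dsub):
                        g = gap_nt(
                            (rts[i].start, rts[i].end), (dvs[j].start, dvs[j].end)
                        )
                        if g is None or g > cfg.max_gap:
                            ok = False
                            break
                        total += g
                    if ok and (best is None or k > best[0] or (k == best[0] and total < best[1])):
                        best = (k, total, set(zip(rsub, dsub)))
            if best is not None and best[0] == k:
                break
        return best

    def test_agrees_on_isolated_pairs(self, rng):
        for trial in range(20):
            rts, dvs = [], []
            pos = 0
            for i in range(int(rng.integers(1, 5))):
                pos += int(rng.integers(3000, 6000))
                rts.append(mk_hit(kind="RT", start=pos, end=pos + 600, qid=f"rt{i}"))
                gap = int(rng.integers(0, 1600))
                dvs.append(
                    mk_hit(kind="DV_VI", start=pos + 600 + gap, end=pos + 690 + gap, qid=f"dv{i}")
                )
                pos += 600 + gap + 90
            calls, _ = pair_rt_with_dvvi(rts, dvs)
            opt = self.brute_force(rts, dvs)
            got = {(rts.index(c.rt_hit), dvs.index(c.dvvi_hit)) for c in calls}
            assert got == opt[2]
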