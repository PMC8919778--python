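"""Assembly of filtered domain hits into intron calls.

An IEP-containing call joins one RT hit with one domain V/VI hit on the same
strand, RT upstream in intron orientation, separated by at most 1,300 nt
(the empirical 99th percentile of RT-to-domain-V distances in curated
introns).  Domain V/VI hits left unpaired can instead be claimed by upstream
domain I-IV evidence under the same distance rule, yielding ORF-less calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .hits import DomainHit
from .io import GenomeRecord


@dataclass(frozen=True)
class AssemblyConfig:
    max_gap: int = 1300
    allow_overlap: bool = True
    require_upstream_order: bool = True
    collapse_duplicated_dvvi: bool = False

    def __post_init__(self) -> None:
        if self.max_gap <= 0:
            raise ValueError("max_gap must be positive")


@dataclass
class IntronCall:
    replicon_id: str
    strand: str
    category: str  # iep_containing | orf_less
    span: tuple[int, int]
    dvvi_hit: Optional[DomainHit] = None
    rt_hit: Optional[DomainHit] = None
    d1_4_hits: list = field(default_factory=list)
    iep_type: Optional[str] = None
    five_prime: Optional[int] = None
    iep_status: Optional[str] = None
    call_id: Optional[str] = None


def gap_nt(
    a: tuple[int, int],
    b: tuple[int, int],
    strand: str = "+",
    topology: str = "linear",
    length: Optional[int] = None,
    require_order: bool = True,
) -> Optional[int]:
    """Nearest-boundary gap from upstream interval a to downstream b.

    Intervals are 0-based half-open on the forward axis; "upstream" means 5'
    in intron orientation (lower coordinates on +, higher on -).  Overlap
    clamps the gap to 0.  On circular replicons the gap wraps the origin;
    when ordering is not required the smaller of the two arc gaps is
    returned.  Returns None when b lies upstream of a and ordering is
    required.
    """
    if strand == "-":
        # mirror onto the strand axis, then identical arithmetic
        if topology == "circular":
            if length is None:
                raise ValueError("circular gap needs replicon length")
            a, b = (length - a[1], length - a[0]), (length - b[1], length - b[0])
        else:
            a, b = (-a[1], -a[0]), (-b[1], -b[0])
    fwd = b[0] - a[1]
    if topology == "circular":
        if length is None:
            raise ValueError("circular gap needs replicon length")
        fwd_arc = fwd % length
        back_arc = (a[0] - b[1]) % length
        if a[0] < b[1] and b[0] < a[1]:  # direct overlap
            return 0
        if require_order:
            return min(fwd_arc, length)  # always defined on a circle
        return min(fwd_arc, back_arc)
    if fwd >= 0:
        return fwd
    if b[1] > a[0]:  # overlap
        return 0
    if require_order:
        return None
    return a[0] - b[1]


def _candidate_pairs(rt_hits, dvvi_hits, cfg, topology, length):
    pairs = []
    for i, rt in enumerate(rt_hits):
        for j, dv in enumerate(dvvi_hits):
            if rt.replicon_id != dv.replicon_id or rt.strand != dv.strand:
                continue
            g = gap_nt(
                (rt.start, rt.end),
                (dv.start, dv.end),
                strand=rt.strand,
                topology=topology,
                length=length,
                require_order=cfg.require_upstream_order,
            )
            if g is not None and g <= cfg.max_gap:
                pairs.append((g, -rt.bit_score, i, j))
    return sorted(pairs)


def _hull(hits) -> tuple[int, int]:
    return min(h.start for h in hits), max(h.end for h in hits)


def pair_rt_with_dvvi(
    rt_hits: list[DomainHit],
    dvvi_hits: list[DomainHit],
    cfg: AssemblyConfig = AssemblyConfig(),
    topology: str = "linear",
    length: Optional[int] = None,
) -> tuple[list[IntronCall], list[DomainHit]]:
    """Greedy smallest-gap pairing of RT with domain V/VI hits.

    Ties on gap break toward the higher RT bit score.  Each hit joins at
    most one call.  Returns (calls, unpaired DV/VI hits).
    """
    used_rt: set[int] = set()
    used_dv: set[int] = set()
    calls = []
    for _g, _negbits, i, j in _candidate_pairs(rt_hits, dvvi_hits, cfg, topology, length):
        if i in used_rt or j in used_dv:
            continue
        used_rt.add(i)
        used_dv.add(j)
        rt, dv = rt_hits[i], dvvi_hits[j]
        calls.append(
            IntronCall(
                replicon_id=rt.replicon_id,
                strand=rt.strand,
                category="iep_containing",
                span=_hull([rt, dv]),
                dvvi_hit=dv,
                rt_hit=rt,
                iep_type=rt.iep_type or "unclassified",
            )
        )
    unpaired = [dv for j, dv in enumerate(dvvi_hits) if j not in used_dv]
    return calls, unpaired


def attach_orfless(
    unpaired_dvvi: list[DomainHit],
    d1_4_hits: list[DomainHit],
    cfg: AssemblyConfig = AssemblyConfig(),
    topology: str = "linear",
    length: Optional[int] = None,
) -> list[IntronCall]:
    """ORF-less calls: unpaired domain V/VI with upstream domain I-IV evidence."""
    calls = []
    for dv in unpaired_dvvi:
        members = []
        for d in d1_4_hits:
            if d.replicon_id != dv.replicon_id or d.strand != dv.strand:
                continue
            g = gap_nt(
                (d.start, d.end),
                (dv.start, dv.end),
                strand=dv.strand,
                topology=topology,
                length=length,
                require_order=cfg.require_upstream_order,
            )
            if g is not None and g <= cfg.max_gap:
                members.append(d)
        if members:
            calls.append(
                IntronCall(
                    replicon_id=dv.replicon_id,
                    strand=dv.strand,
                    category="orf_less",
                    span=_hull(members + [dv]),
                    dvvi_hit=dv,
                    d1_4_hits=sorted(members, key=lambda h: h.start),
                )
            )
    return calls


def merge_dvvi_hits(dvvi_hits: list[DomainHit]) -> list[DomainHit]:
    """Collapse overlapping same-strand DV/VI hits, keeping the highest bits."""
    from .hits import _overlap_groups

    return sorted(
        (max(g, key=lambda h: h.bit_score) for g in _overlap_groups(dvvi_hits)),
        key=lambda h: (h.replicon_id, h.start),
    )


def call_introns(
    genome: GenomeRecord,
    hits: list[DomainHit],
    cfg: AssemblyConfig = AssemblyConfig(),
) -> list[IntronCall]:
    """Run the assembly steps for one replicon and return sorted calls."""
    mine = [h for h in hits if h.replicon_id == genome.replicon_id]
    rt = [h for h in mine if h.kind == "RT"]
    dvvi = merge_dvvi_hits([h for h in mine if h.kind == "DV_VI"])
    d1_4 = [h for h in mine if h.kind in ("D1", "D2", "D3", "D4")]
    calls, unpaired = pair_rt_with_dvvi(rt, dvvi, cfg, genome.topology, genome.length)
    calls += attach_orfless(unpaired, d1_4, cfg, genome.topology, genome.length)
    if cfg.collapse_duplicated_dvvi:
        by_rt: dict[int, IntronCall] = {}
        kept = []
        for c in calls:
            key = id(c.rt_hit) if c.rt_hit is not None else None
            if key is not None and key in by_rt:
                prev = by_rt[key]
                prev.span = (min(prev.span[0], c.span[0]), max(prev.span[1], c.span[1]))
                continue
            if key is not None:
                by_rt[key] = c
            kept.append(c)
        calls = kept
    calls.sort(key=lambda c: c.span)
    for i, c in enumerate(calls):
        if c.call_id is None:
            c.call_id = f"{genome.replicon_id}:g2i_{i + 1:04d}"
    return calls
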