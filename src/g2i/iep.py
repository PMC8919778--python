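"""Intron-encoded protein (IEP) analysis.

For every IEP-containing call the surrounding nucleotide region (1,000 nt
upstream of the RT hit to 200 nt downstream of the domain V/VI hit, in
intron orientation) is extracted and the encoded protein reconstructed.
Proteins are classified as

* ``interrupted`` - at least one stop codon strictly inside the aligned
  reference span (pseudogenised reading frames),
* ``short_orf``  - an intact frame missing at least 5 of the 15 conserved
  peptide motifs expected for the IEP type (large domain deletions),
* ``canonical``  - everything else.

Interrupted takes precedence: interrupted frames are set aside before any
ORF/motif analysis, mirroring the disjoint treatment of the two
non-canonical classes.  All translation uses genetic code table 11 with
ATG/GTG/TTG accepted as start codons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import edlib
from Bio.Seq import Seq

from . import _align
from .assembly import IntronCall
from .io import GenomeRecord, revcomp

log = logging.getLogger("g2i")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

UPSTREAM_NT = 1000
DOWNSTREAM_NT = 200

N_MOTIFS = 15
SHORT_ORF_MISSING_MIN = 5
MOTIF_MATCH_FRAC = 0.6  # fraction of a motif's max (self) score counted present


@dataclass
class MotifSet:
    """The 15 conserved peptide motifs (10-50 aa each) of one IEP type."""

    iep_type: str
    motifs: list[str]
    match_frac: float = MOTIF_MATCH_FRAC

    def __post_init__(self) -> None:
        if len(self.motifs) != N_MOTIFS:
            raise ValueError(f"need exactly {N_MOTIFS} motifs, got {len(self.motifs)}")
        for m in self.motifs:
            if not 10 <= len(m) <= 50:
                raise ValueError(f"motif length {len(m)} outside [10,50]")


@dataclass
class IEPRecord:
    call_ref: str
    region: str
    aa_seq: str = ""
    frame_offset: int = 0
    status: str = "canonical"
    motif_presence: list = field(default_factory=lambda: [False] * N_MOTIFS)
    n_missing_motifs: int = N_MOTIFS
    internal_stop_positions: list = field(default_factory=list)
    orf: Optional[tuple[int, int]] = None
    orf_genome_start: Optional[int] = None  # genome coord of the ORF's 5' base
    error: Optional[str] = None


def extract_iep_region(call: IntronCall, genome: GenomeRecord) -> tuple[str, int]:
    """Region around the IEP, in intron orientation.

    Returns (sequence, rt_offset): rt_offset is the position of the RT hit's
    first base within the returned sequence.  Clamped at the ends of linear
    replicons; wraps the origin of circular ones.
    """
    if call.category != "iep_containing" or call.rt_hit is None or call.dvvi_hit is None:
        raise ValueError("IEP region needs an iep_containing call with member hits")
    rt, dv = call.rt_hit, call.dvvi_hit
    L = genome.length
    if call.strand == "+":
        lo, hi = rt.start - UPSTREAM_NT, dv.end + DOWNSTREAM_NT
    else:
        lo, hi = dv.start - DOWNSTREAM_NT, rt.end + UPSTREAM_NT
    if genome.topology == "circular":
        seq = "".join(genome.sequence[i % L] for i in range(lo, hi))
    else:
        lo_c, hi_c = max(0, lo), min(L, hi)
        seq = genome.sequence[lo_c:hi_c]
        lo = lo_c
        hi = hi_c
    if not seq:
        raise ValueError("degenerate empty IEP region")
    rt_offset = rt.start - lo if call.strand == "+" else hi - rt.end
    return (seq if call.strand == "+" else revcomp(seq), rt_offset)


def locate_iep(
    region: str, references: dict[str, str], min_bits: float = 40.0
) -> Optional[tuple[str, int, str, tuple[int, int]]]:
    """Best translated local alignment of reference IEP peptides to the region.

    Returns (subject peptide, frame_offset, best query id, nt span of the
    subject within the region) or None when nothing clears the floor score;
    the caller then falls back to the RT reading frame.  The subject peptide
    may contain '*' where the reading frame is interrupted.
    """
    raw = _align.search_protein(region, references, min_bits)
    fwd = [h for h in raw if h.strand == "+"]
    if not fwd:
        return None
    best = max(fwd, key=lambda h: h.bit_score)
    aa = str(Seq(region[best.start : best.start + 3 * ((best.end - best.start) // 3)]).translate(table=11))
    return aa, best.frame, best.query_id, (best.start, best.end)


def detect_interrupted(region: str, subject_span: tuple[int, int], frame_offset: int) -> list[int]:
    """Indices (in codons from the span start) of internal stop codons.

    A stop at the final codon of the span is terminal, not internal.
    """
    s0, s1 = subject_span
    if (s0 - frame_offset) % 3:
        raise ValueError("subject span is not in the stated frame")
    codons = [region[i : i + 3] for i in range(s0, s1 - 2, 3)]
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS]
    return [i for i in stops if i < len(codons) - 1]


def find_orf(
    region: str, rt_interval: tuple[int, int]
) -> tuple[int, int, str]:
    """Longest ORF overlapping the RT hit, scanned in intron orientation.

    Within each frame the region is split at stop codons; in each stop-free
    segment the ORF runs from the first ATG/GTG/TTG to the segment's stop
    (kept as long as possible, so an upstream in-frame start can extend the
    ORF past the true translation initiation site).  Returns (start, end,
    aa_seq) with nt coordinates in the region; aa_seq excludes the stop.
    """
    if len(region) < 60:
        raise ValueError("region too short for ORF search")
    best: Optional[tuple[int, int, str]] = None
    for f in range(3):
        n_codons = (len(region) - f) // 3
        codons = [region[f + 3 * i : f + 3 * i + 3] for i in range(n_codons)]
        seg_start = 0
        boundaries = [i for i, c in enumerate(codons) if c in STOP_CODONS] + [n_codons]
        for stop_i in boundaries:
            seg = range(seg_start, stop_i)
            start_codon = next((i for i in seg if codons[i] in START_CODONS), None)
            seg_start = stop_i + 1
            if start_codon is None:
                continue
            orf_end_codon = stop_i + 1 if stop_i < n_codons else n_codons
            nt0 = f + 3 * start_codon
            nt1 = f + 3 * orf_end_codon
            if not (nt0 < rt_interval[1] and rt_interval[0] < nt1):
                continue
            aa = str(Seq(region[nt0:nt1]).translate(table=11)).rstrip("*")
            assert (nt1 - nt0) % 3 == 0
            if best is None or (nt1 - nt0) > (best[1] - best[0]):
                best = (nt0, nt1, aa)
    if best is None:
        raise ValueError("no ORF overlapping the RT domain")
    return best


def motif_completeness(aa_seq: str, motifs: MotifSet) -> tuple[list[bool], int]:
    """Best ungapped local match of each motif against the peptide.

    A motif counts as present when its best window identity score reaches
    match_frac of the motif's self-score (= its length, with +1 per
    identical residue).
    """
    if not aa_seq:
        raise ValueError("empty peptide")
    presence = []
    for m in motifs.motifs:
        need = motifs.match_frac * len(m)
        best = 0
        for off in range(len(aa_seq) - len(m) + 1):
            window = aa_seq[off : off + len(m)]
            score = sum(a == b for a, b in zip(window, m))
            if score > best:
                best = score
        presence.append(best >= need)
    return presence, presence.count(False)


def classify_iep(record: IEPRecord) -> str:
    """interrupted > short_orf > canonical."""
    if record.internal_stop_positions:
        return "interrupted"
    if record.n_missing_motifs >= SHORT_ORF_MISSING_MIN:
        return "short_orf"
    return "canonical"


def strip_stops(aa_seq: str) -> str:
    """Drop stop characters before clustering (length shrinks by their count)."""
    return aa_seq.replace("*", "")


def analyze_iep(
    call: IntronCall,
    genome: GenomeRecord,
    references: dict[str, str],
    motif_sets: dict[str, MotifSet],
) -> IEPRecord:
    """Full IEP workup for one call: locate, interruption scan, ORF, motifs."""
    region, rt_off = extract_iep_region(call, genome)
    rec = IEPRecord(call_ref=call.call_id or "", region=region)
    located = locate_iep(region, references)
    rt_len = call.rt_hit.end - call.rt_hit.start
    if located is not None:
        aa, frame, _qid, span = located
        rec.frame_offset = frame
        rec.internal_stop_positions = detect_interrupted(region, span, frame)
        if rec.internal_stop_positions:
            rec.aa_seq = aa
            rec.status = "interrupted"
            return rec
    try:
        nt0, nt1, aa = find_orf(region, (rt_off, rt_off + rt_len))
    except ValueError as exc:
        rec.error = str(exc)
        rec.status = "canonical"
        return rec
    rec.orf = (nt0, nt1)
    if call.strand == "+":
        rec.orf_genome_start = (call.rt_hit.start - rt_off) + nt0
    else:
        rec.orf_genome_start = (call.rt_hit.end + rt_off) - 1 - nt0
    rec.frame_offset = nt0 % 3
    rec.aa_seq = aa
    mset = motif_sets.get(call.iep_type)
    if mset is not None:
        rec.motif_presence, rec.n_missing_motifs = motif_completeness(aa, mset)
    else:
        rec.motif_presence, rec.n_missing_motifs = [True] * N_MOTIFS, 0
    rec.status = classify_iep(rec)
    return rec


# ---------------------------------------------------------------------------
# Greedy incremental clustering (CD-HIT-style)
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    representative: str
    members: list[str]
    identity_threshold: float = 0.85


def pairwise_identity(a: str, b: str) -> float:
    """Identity with the shorter sequence as denominator.

    The shorter sequence is aligned inside the longer (edlib infix mode,
    free end gaps in the longer sequence); identity = 1 - edits/|shorter|.
    """
    if not a or not b:
        return 0.0
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    d = edlib.align(short, long_, mode="HW")["editDistance"]
    return max(0.0, 1.0 - d / len(short))


def greedy_cluster(
    seqs: dict[str, str], threshold: float = 0.85
) -> list[Cluster]:
    """Longest-first greedy incremental clustering.

    Each sequence joins the first existing cluster whose representative it
    matches at >= threshold identity, else founds a new cluster.  Ties in
    length break lexicographically on the id, so the partition is
    deterministic.
    """
    if not seqs:
        raise ValueError("nothing to cluster")
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    clusters: list[Cluster] = []
    for sid in order:
        for cl in clusters:
            if pairwise_identity(seqs[sid], seqs[cl.representative]) >= threshold:
                cl.members.append(sid)
                break
        else:
            clusters.append(Cluster(representative=sid, members=[sid], identity_threshold=threshold))
    return clusters
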