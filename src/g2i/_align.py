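"""Seed-and-extend local alignment against a replicon.

Candidate loci are found by exact k-mer seeding (two seeds on nearby
diagonals for translated searches, one seed for nucleotide searches) and each
candidate window is then rescored with a Smith-Waterman local alignment
(Bio.Align.PairwiseAligner).  Scores are converted to bits and a pseudo
e-value with fixed Karlin-Altschul constants; these are fixture-scale
stand-ins, never comparable with e-values from external search tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .io import revcomp

# fixed Karlin-Altschul-style constants for the pseudo statistics
_PROT_LAMBDA, _PROT_K = 0.267, 0.041
_NUC_LAMBDA, _NUC_K = 0.625, 0.41

_PROT_SEED_K = 4
_NUC_SEED_K = 11
_DIAG_BAND = 4

_AA_OK = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class RawHit:
    query_id: str
    strand: str
    start: int  # 0-based half-open, forward genome axis
    end: int
    score: float
    bit_score: float
    evalue: float
    query_coverage: float
    frame: int = 0


def _protein_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a


def _nucleotide_aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "local"
    a.match_score = 2.0
    a.mismatch_score = -3.0
    a.open_gap_score = -5.0
    a.extend_gap_score = -2.0
    return a


def _sanitize_aa(aa: str) -> str:
    return "".join(c if c in _AA_OK or c == "*" else "X" for c in aa)


def translate_frames(nt: str):
    """Six-frame translation, genetic code table 11.

    Yields (strand, frame_offset, aa_string); frame offsets refer to the
    strand-oriented sequence (the reverse complement for the minus strand).
    """
    for strand, s in (("+", nt), ("-", revcomp(nt))):
        for f in range(3):
            sub = s[f : f + 3 * ((len(s) - f) // 3)]
            if not sub:
                continue
            aa = str(Seq(sub).translate(table=11))
            yield strand, f, _sanitize_aa(aa)


def _bits(score: float, lam: float, k: float) -> float:
    return (lam * score - math.log(k)) / math.log(2.0)


def _evalue(score: float, lam: float, k: float, m: int, n: int) -> float:
    return k * m * n * math.exp(-lam * score)


def _seed_index(queries: dict[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    idx: dict[str, list[tuple[str, int]]] = {}
    for qid, q in queries.items():
        for i in range(len(q) - k + 1):
            idx.setdefault(q[i : i + k], []).append((qid, i))
    return idx


def _candidate_windows(subject: str, idx, k: int, qlens: dict[str, int], min_seeds: int):
    """Group seed matches by (query, diagonal band); return candidate spans."""
    by_key: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for s in range(len(subject) - k + 1):
        for qid, qpos in idx.get(subject[s : s + k], ()):
            band = (s - qpos) // (_DIAG_BAND + 1)
            by_key.setdefault((qid, band), []).append((s, qpos))
            by_key.setdefault((qid, band + 1), []).append((s, qpos))
    out = []
    seen = set()
    for (qid, _band), matches in by_key.items():
        if len(matches) < min_seeds:
            continue
        s_lo = min(m[0] for m in matches)
        s_hi = max(m[0] for m in matches) + k
        pad = qlens[qid] + 10
        key = (qid, s_lo // pad)
        if key in seen:
            continue
        seen.add(key)
        out.append((qid, max(0, s_lo - pad), min(len(subject), s_hi + pad)))
    return out


def _align_window(aligner, subject_window: str, query: str):
    alns = aligner.align(subject_window, query)
    if len(alns) == 0:
        return None
    aln = alns[0]
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    return (
        aln.score,
        int(t_blocks[0][0]),
        int(t_blocks[-1][1]),
        int(q_blocks[0][0]),
        int(q_blocks[-1][1]),
    )


def _suppress_overlaps(hits: list[RawHit]) -> list[RawHit]:
    hits = sorted(hits, key=lambda h: -h.score)
    kept: list[RawHit] = []
    for h in hits:
        if any(
            k.query_id == h.query_id
            and k.strand == h.strand
            and h.start < k.end
            and k.start < h.end
            for k in kept
        ):
            continue
        kept.append(h)
    return sorted(kept, key=lambda h: (h.start, h.query_id))


def search_protein(subject_nt: str, queries: dict[str, str], min_bits: float) -> list[RawHit]:
    """Translated (tblastn-like) search of peptide queries vs a nucleotide subject."""
    for qid, q in queries.items():
        if not set(q) <= _AA_OK:
            raise ValueError(f"query {qid!r} is not a plain peptide sequence")
    aligner = _protein_aligner()
    idx = _seed_index(queries, _PROT_SEED_K)
    qlens = {qid: len(q) for qid, q in queries.items()}
    L = len(subject_nt)
    hits: list[RawHit] = []
    for strand, frame, aa in translate_frames(subject_nt):
        for qid, w_lo, w_hi in _candidate_windows(aa, idx, _PROT_SEED_K, qlens, min_seeds=2):
            res = _align_window(aligner, aa[w_lo:w_hi], queries[qid])
            if res is None:
                continue
            score, t0, t1, q0, q1 = res
            aa0, aa1 = w_lo + t0, w_lo + t1
            nt0, nt1 = frame + 3 * aa0, frame + 3 * aa1
            if strand == "-":
                nt0, nt1 = L - nt1, L - nt0
            bits = _bits(score, _PROT_LAMBDA, _PROT_K)
            if bits < min_bits:
                continue
            hits.append(
                RawHit(
                    query_id=qid,
                    strand=strand,
                    start=nt0,
                    end=nt1,
                    score=score,
                    bit_score=bits,
                    evalue=_evalue(score, _PROT_LAMBDA, _PROT_K, qlens[qid], L),
                    query_coverage=(q1 - q0) / qlens[qid],
                    frame=frame,
                )
            )
    return _suppress_overlaps(hits)


def search_nucleotide(subject_nt: str, queries: dict[str, str], min_bits: float) -> list[RawHit]:
    """blastn-like search of nucleotide queries vs a nucleotide subject."""
    for qid, q in queries.items():
        if not set(q) <= set("ACGTN"):
            raise ValueError(f"query {qid!r} is not a nucleotide sequence")
    aligner = _nucleotide_aligner()
    qlens = {qid: len(q) for qid, q in queries.items()}
    L = len(subject_nt)
    hits: list[RawHit] = []
    for strand in ("+", "-"):
        qset = {qid: (q if strand == "+" else revcomp(q)) for qid, q in queries.items()}
        idx = _seed_index(qset, _NUC_SEED_K)
        for qid, w_lo, w_hi in _candidate_windows(
            subject_nt, idx, _NUC_SEED_K, qlens, min_seeds=1
        ):
            res = _align_window(aligner, subject_nt[w_lo:w_hi], qset[qid])
            if res is None:
                continue
            score, t0, t1, q0, q1 = res
            bits = _bits(score, _NUC_LAMBDA, _NUC_K)
            if bits < min_bits:
                continue
            hits.append(
                RawHit(
                    query_id=qid,
                    strand=strand,
                    start=w_lo + t0,
                    end=w_lo + t1,
                    score=score,
                    bit_score=bits,
                    evalue=_evalue(score, _NUC_LAMBDA, _NUC_K, qlens[qid], L),
                    query_coverage=(q1 - q0) / qlens[qid],
                )
            )
    return _suppress_overlaps(hits)
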