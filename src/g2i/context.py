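"""Genomic context of intron calls: 5' ends and transcription terminators.

The intron 5' end is located by scanning a per-IEP-type log-odds profile
(position weight matrix over A/C/G/T, uniform background) across the 1,200
nt upstream of the IEP, keeping the best window scoring >= 10 bits.  The
distance from that 5' end to the 3' end of the nearest upstream
rho-independent terminator is then measured, and terminators themselves are
classed L-shaped (>= 4 U residues in the tail just after the stem-loop) or
I-shaped (everything else).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .assembly import IntronCall
from .io import GenomeRecord, TerminatorRecord, revcomp

PROFILE_MIN_BITS = 10.0
FIVE_PRIME_WINDOW = 1200
TAIL_NT = 10
L_SHAPE_MIN_T = 4
MAX_TERM_SEARCH = 5000

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

# which published consensus profile serves which IEP type (none for G [g1])
PROFILE_FOR_TYPE = {
    "A": "A",
    "B": "B",
    "C": "C",
    "D": "D",
    "E": "E",
    "F_g2_g5": "F_g2_g5",
    "ML": "ML",
    "CL1A": "CL1",
    "CL1B": "CL1",
    "CL2A": "CL2",
    "CL2B": "CL2",
}


@dataclass
class FivePrimeProfile:
    iep_type: str
    logodds: np.ndarray  # (L, 4), bits vs uniform background
    min_bits: float = PROFILE_MIN_BITS

    def __post_init__(self) -> None:
        self.logodds = np.asarray(self.logodds, dtype=float)
        if self.logodds.ndim != 2 or self.logodds.shape[1] != 4:
            raise ValueError("log-odds matrix must be (L, 4)")
        if len(self.logodds) < 8:
            raise ValueError("profile shorter than 8 columns")
        if not np.isfinite(self.logodds).all():
            raise ValueError("non-finite log-odds")

    def __len__(self) -> int:
        return len(self.logodds)


def build_profile(
    alignment: list[str], iep_type: str, pseudocount: float = 0.1
) -> FivePrimeProfile:
    """Log-odds profile from an aligned set of 5'-end consensus sequences.

    Per column: log2((count+pseudocount)/(total+4*pseudocount)/0.25), gaps
    excluded from the counts; columns that are all gaps are dropped.
    """
    if not alignment:
        raise ValueError("empty alignment")
    ncol = len(alignment[0])
    if any(len(s) != ncol for s in alignment):
        raise ValueError("alignment rows differ in length")
    cols = []
    for j in range(ncol):
        counts = np.full(4, pseudocount)
        n = 0
        for s in alignment:
            c = s[j].upper()
            if c in _BASE_IDX:
                counts[_BASE_IDX[c]] += 1
                n += 1
        if n == 0:
            continue  # all-gap column dropped
        freqs = counts / counts.sum()
        cols.append(np.log2(freqs / 0.25))
    return FivePrimeProfile(iep_type=iep_type, logodds=np.vstack(cols))


def score_window(profile: FivePrimeProfile, window: str) -> float:
    """Profile score in bits; N contributes the background (0 bits)."""
    total = 0.0
    for j, c in enumerate(window):
        i = _BASE_IDX.get(c)
        if i is not None:
            total += profile.logodds[j, i]
    return total


def scan_profile(profile: FivePrimeProfile, seq: str) -> list[tuple[int, float]]:
    """All window scores over a strand-oriented sequence."""
    L = len(profile)
    return [(i, score_window(profile, seq[i : i + L])) for i in range(len(seq) - L + 1)]


def locate_5prime(
    call: IntronCall,
    genome: GenomeRecord,
    profiles: dict[str, FivePrimeProfile],
    iep_start: Optional[int] = None,
    window: int = FIVE_PRIME_WINDOW,
) -> Optional[int]:
    """Genome coordinate (0-based, 5'-terminal base) of the intron 5' end.

    Scans within `window` nt upstream of the IEP start in intron
    orientation; the best window with score >= min_bits wins.  Calls of type
    G [g1] always return None (no published consensus).  iep_start defaults
    to the strand-wise start of the RT hit.
    """
    if call.iep_type == "G_g1":
        return None
    key = PROFILE_FOR_TYPE.get(call.iep_type or "")
    profile = profiles.get(key) if key else None
    if profile is None:
        return None
    if iep_start is None:
        if call.rt_hit is None:
            return None
        iep_start = call.rt_hit.start if call.strand == "+" else call.rt_hit.end - 1
    if call.strand == "+":
        lo = max(0, iep_start - window)
        seq = genome.sequence[lo:iep_start]
    else:
        hi = min(genome.length, iep_start + 1 + window)
        seq = revcomp(genome.sequence[iep_start + 1 : hi])
    best_pos, best_score = None, -math.inf
    for i, s in scan_profile(profile, seq):
        if s > best_score:
            best_pos, best_score = i, s
    if best_pos is None or best_score < profile.min_bits:
        return None
    if call.strand == "+":
        return lo + best_pos
    return hi - 1 - best_pos


def classify_terminator_shape(term: TerminatorRecord, genome: GenomeRecord) -> str:
    """L if the 10-nt tail right after the stem-loop has >= 4 T, else I."""
    if term.strand == "+":
        tail = genome.sequence[term.stem_end + 1 : term.stem_end + 1 + TAIL_NT]
    else:
        tail = revcomp(genome.sequence[max(0, term.stem_start - TAIL_NT) : term.stem_start])
    return "L" if tail.count("T") >= L_SHAPE_MIN_T else "I"


def terminator_distance(
    call_5prime: int,
    strand: str,
    terms: list[TerminatorRecord],
    max_search: int = MAX_TERM_SEARCH,
    replicon_id: Optional[str] = None,
) -> Optional[tuple[int, TerminatorRecord]]:
    """Distance to the nearest upstream same-strand terminator 3' end.

    Distance = (intron 5' base) - (terminator 3' base) along the strand
    axis, >= 0; None when no terminator lies within max_search.
    """
    best: Optional[tuple[int, TerminatorRecord]] = None
    for t in terms:
        if t.strand != strand:
            continue
        if replicon_id is not None and t.replicon_id != replicon_id:
            continue
        d = call_5prime - t.term_3prime if strand == "+" else t.term_3prime - call_5prime
        if d < 0 or d > max_search:
            continue
        if best is None or d < best[0]:
            best = (d, t)
    return best


DISTANCE_BINS = [0, 100, 200, 300, 400, 500, 600, 700, 800, 900, 1000]


def bin_distance(d: int) -> str:
    """Histogram bin label (0-100, 101-200, ..., >1000)."""
    if d < 0:
        raise ValueError("negative distance")
    if d > 1000:
        return ">1000"
    i = 0 if d <= 100 else (d - 1) // 100
    return "0-100" if i == 0 else f"{i * 100 + 1}-{(i + 1) * 100}"
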