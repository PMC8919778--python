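"""Domain-hit evidence: parsing, filtering, IEP typing.

A group II intron leaves three kinds of searchable footprints in a genome:
the reverse-transcriptase (RT) domain of its intron-encoded protein, the
catalytic RNA domains V-VI, and the upstream RNA domains I-IV.  Evidence for
each arrives as tabular output of external homology searches (12-column
protein-vs-nucleotide tables, or covariance-model tblout), or from the
built-in scanner so that fixtures need no external tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

from . import _align
from .io import GenomeRecord

log = logging.getLogger("g2i")

IEP_TYPES = (
    "A",
    "B",
    "C",
    "D",
    "E",
    "G_g1",
    "F_g2_g5",
    "g6",
    "ML",
    "CL1A",
    "CL1B",
    "CL2A",
    "CL2B",
    "U1",
    "U2",
    "U3",
    "unclassified",
)

HIT_KINDS = ("RT", "DV_VI", "D1", "D2", "D3", "D4")


@dataclass
class DomainHit:
    """One evidence interval, 0-based half-open on the forward strand."""

    replicon_id: str
    kind: str
    start: int
    end: int
    strand: str
    bit_score: float
    evalue: float
    query_id: str
    query_coverage: float
    iep_type: Optional[str] = None
    source: str = "alignment"  # alignment | cm

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty hit interval [{self.start},{self.end})")
        if self.kind not in HIT_KINDS:
            raise ValueError(f"unknown hit kind {self.kind!r}")


@dataclass(frozen=True)
class FilterConfig:
    """Evidence thresholds; comparison directions follow the field notes."""

    rt_evalue_max: float = 1e-10  # keep iff evalue <= this
    rt_qcov_min: float = 0.40  # keep iff coverage > this (strict)
    dvvi_bits_min: float = 24.0  # keep iff bits > this (strict)
    d1_4_blast_evalue_max: float = 1e-10
    d1_4_blast_qcov_min: float = 0.60  # strict
    d1_4_cm_evalue_max: float = 1e-2


def parse_hit_table(
    path: str,
    dialect: str,
    kind: str,
    query_meta: Optional[dict] = None,
) -> list[DomainHit]:
    """Parse an external search hit table into DomainHits.

    dialect "protein_tabular": 12-column tabular (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore); subject
    coordinates are 1-based inclusive, reversed for minus-strand hits.
    dialect "cm_tblout": Infernal-style tblout.

    query_meta maps query_id to a dict with "length" (required to compute
    query coverage for tabular hits) and optionally "iep_type".
    """
    query_meta = query_meta or {}
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            try:
                if dialect == "protein_tabular":
                    if len(f) < 12:
                        raise ValueError("fewer than 12 columns")
                    qid, sid = f[0], f[1]
                    qstart, qend = int(f[6]), int(f[7])
                    sstart, send = int(f[8]), int(f[9])
                    evalue, bits = float(f[10]), float(f[11])
                    strand = "+" if sstart <= send else "-"
                    start, end = (min(sstart, send) - 1, max(sstart, send))
                    meta = query_meta.get(qid)
                    if meta and meta.get("length"):
                        cov = (abs(qend - qstart) + 1) / meta["length"]
                    else:
                        cov = 1.0
                    hits.append(
                        DomainHit(
                            replicon_id=sid,
                            kind=kind,
                            start=start,
                            end=end,
                            strand=strand,
                            bit_score=bits,
                            evalue=evalue,
                            query_id=qid,
                            query_coverage=min(cov, 1.0),
                            source="alignment",
                        )
                    )
                elif dialect == "cm_tblout":
                    if len(f) < 16:
                        raise ValueError("fewer than 16 columns")
                    sid, qid = f[0], f[2]
                    mdl_from, mdl_to = int(f[5]), int(f[6])
                    seq_from, seq_to = int(f[7]), int(f[8])
                    strand = f[9]
                    bits, evalue = float(f[14]), float(f[15])
                    start, end = (min(seq_from, seq_to) - 1, max(seq_from, seq_to))
                    meta = query_meta.get(qid)
                    if meta and meta.get("length"):
                        cov = (abs(mdl_to - mdl_from) + 1) / meta["length"]
                    else:
                        cov = 1.0
                    hits.append(
                        DomainHit(
                            replicon_id=sid,
                            kind=kind,
                            start=start,
                            end=end,
                            strand=strand,
                            bit_score=bits,
                            evalue=evalue,
                            query_id=qid,
                            query_coverage=min(cov, 1.0),
                            source="cm",
                        )
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as exc:
                if "unknown dialect" in str(exc):
                    raise
                log.warning("%s line %d: malformed row skipped (%s)", path, lineno, exc)
    return hits


def _attach_types(hits: list[DomainHit], query_meta: dict) -> list[DomainHit]:
    out = []
    for h in hits:
        meta = query_meta.get(h.query_id)
        if meta is None:
            raise ValueError(f"unknown query_id {h.query_id!r} for IEP typing")
        out.append(replace(h, iep_type=meta.get("iep_type", "unclassified")))
    return out


def _overlap_groups(hits: list[DomainHit]):
    """Chains of same-replicon, same-strand hits overlapping by >=1 nt."""
    hits = sorted(hits, key=lambda h: (h.replicon_id, h.strand, h.start, h.end))
    group: list[DomainHit] = []
    for h in hits:
        if group and (
            h.replicon_id == group[-1].replicon_id
            and h.strand == group[-1].strand
            and h.start < max(g.end for g in group)
        ):
            group.append(h)
        else:
            if group:
                yield group
            group = [h]
    if group:
        yield group


def filter_and_type_rt_hits(
    hits: list[DomainHit],
    cfg: FilterConfig = FilterConfig(),
    query_meta: Optional[dict] = None,
) -> list[DomainHit]:
    """Apply the RT evidence thresholds and collapse co-located hits.

    Hits must pass evalue <= rt_evalue_max and coverage > rt_qcov_min
    (strict).  Surviving hits that overlap on the same strand are collapsed
    to the single hit with the highest bit score, whose query determines the
    IEP type of the locus.
    """
    kept = [
        h
        for h in hits
        if h.kind == "RT"
        and h.evalue <= cfg.rt_evalue_max
        and h.query_coverage > cfg.rt_qcov_min
    ]
    if query_meta is not None:
        kept = _attach_types(kept, query_meta)
    out = []
    for group in _overlap_groups(kept):
        best = max(group, key=lambda h: h.bit_score)
        if best.iep_type is None:
            best = replace(best, iep_type="unclassified")
        out.append(best)
    return sorted(out, key=lambda h: (h.replicon_id, h.start))


def filter_structural_hits(
    hits: list[DomainHit], cfg: FilterConfig = FilterConfig()
) -> list[DomainHit]:
    """Apply the RNA-domain thresholds.

    Domains V/VI are kept iff bit score > 24 (strict).  Domains I-IV are kept
    iff either the alignment evidence passes (evalue <= 1e-10 and coverage
    > 0.60, strict) or the covariance-model evidence passes (evalue <= 1e-2).
    """
    out = []
    for h in hits:
        if h.kind == "DV_VI":
            if h.bit_score > cfg.dvvi_bits_min:
                out.append(h)
        elif h.kind in ("D1", "D2", "D3", "D4"):
            if h.source == "alignment":
                if h.evalue <= cfg.d1_4_blast_evalue_max and h.query_coverage > cfg.d1_4_blast_qcov_min:
                    out.append(h)
            else:
                if h.evalue <= cfg.d1_4_cm_evalue_max:
                    out.append(h)
    return sorted(out, key=lambda h: (h.replicon_id, h.start))


def builtin_local_search(
    genome: GenomeRecord,
    queries: dict[str, str],
    mode: str,
    score_min: float,
    kind: str = "RT",
    query_meta: Optional[dict] = None,
) -> list[DomainHit]:
    """Local-alignment scan of a replicon with the built-in aligner.

    mode "translated" searches peptide queries against all six reading
    frames (genetic code table 11); mode "nucleotide" searches both strands
    directly.  score_min is a bit-score floor.  Reported e-values are
    pseudo-e-values from fixed Karlin-Altschul constants: they keep the
    FilterConfig thresholds exercisable offline and are never comparable
    with e-values of external tools.
    """
    if mode == "translated":
        raw = _align.search_protein(genome.sequence, queries, score_min)
    elif mode == "nucleotide":
        raw = _align.search_nucleotide(genome.sequence, queries, score_min)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for r in raw:
        meta = (query_meta or {}).get(r.query_id, {})
        out.append(
            DomainHit(
                replicon_id=genome.replicon_id,
                kind=kind,
                start=r.start,
                end=r.end,
                strand=r.strand,
                bit_score=r.bit_score,
                evalue=r.evalue,
                query_id=r.query_id,
                query_coverage=r.query_coverage,
                iep_type=meta.get("iep_type"),
                source="alignment",
            )
        )
    return out
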