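"""Synthetic genomes with planted group II introns and truth tables.

Every pipeline stage is testable offline: genomes carry planted
IEP-containing introns (optionally with internal stop codons or deleted
motifs), ORF-less introns, decoys for each false-call mode, rho-independent
terminators, and a tunable two-replichore GC-skew signal.  Planting emits
both ready-made hit tables (as if produced by external search tools) and the
raw sequence for the built-in scanner, together with a truth table recording
the expected call outcomes.

The parts library (RT peptides per IEP type, the 15 conserved motifs per
type, RNA-domain nucleotide motifs, 5'-end consensus alignments) is
synthetic: generated deterministically from a fixed internal seed, with no
relationship to real intron sequences beyond its statistical shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .assembly import AssemblyConfig
from .context import PROFILE_FOR_TYPE, FivePrimeProfile, build_profile
from .hits import DomainHit
from .iep import MotifSet, N_MOTIFS
from .io import GenomeRecord, TerminatorRecord, revcomp

_PARTS_SEED = 20_220_228
_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

# motif indices 4..10 (0-based) form the RT domain; the flanks are deletable
_RT_MOTIF_LO, _RT_MOTIF_HI = 4, 10
_DELETABLE = [14, 13, 12, 11, 3, 2, 1, 0]

_LINKER_AA = 3
_PAD_AA = 8

DVVI_LEN = 90
D_MOTIF_LEN = 150
FIVE_PRIME_LEN = 36
SPACER_5P = 150
STEM_ARM = 12
STEM_LOOP = 5
TAIL_LEN = 10


def _codon_map() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    out: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


_CODONS = _codon_map()


def reverse_translate(peptide: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide)


def _rand_pep(rng: np.random.Generator, n: int) -> str:
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), n))


def _rand_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[i] for i in rng.integers(0, 4, n))


def _mutate_pep(pep: str, frac: float, rng: np.random.Generator) -> str:
    out = list(pep)
    for i in rng.choice(len(pep), size=max(1, int(frac * len(pep))), replace=False):
        out[i] = _AA[rng.integers(len(_AA))]
    return "".join(out)


def _mutate_nt(seq: str, frac: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in rng.choice(len(seq), size=max(1, int(frac * len(seq))), replace=False):
        out[i] = _NT[rng.integers(4)]
    return "".join(out)


@dataclass
class PartsLibrary:
    motif_sets: dict[str, MotifSet]
    iep_peptides: dict[str, str]  # canonical full IEP peptide per type
    motif_aa_spans: dict[str, list[tuple[int, int]]]  # motif positions in the peptide
    rt_aa_span: dict[str, tuple[int, int]]  # RT domain within the peptide
    rt_queries: dict[str, str]  # reference RT peptides (one per type, the search queries)
    rt_variants: dict[str, list[str]]  # ~5 per type, mutated copies
    dvvi_motif: str
    d_motifs: dict[str, str]  # D1..D4 nucleotide motifs
    five_prime_alignments: dict[str, list[str]]  # per profile key
    five_prime_consensus: dict[str, str]

    def iep_references(self) -> dict[str, str]:
        return {f"IEP_{t}": p for t, p in self.iep_peptides.items()}

    def rt_query_meta(self) -> dict:
        return {
            f"RT_{t}": {"length": len(q), "iep_type": t} for t, q in self.rt_queries.items()
        }

    def profiles(self) -> dict[str, FivePrimeProfile]:
        return {
            key: build_profile(alignment, key)
            for key, alignment in self.five_prime_alignments.items()
        }


def parts_library(types: Optional[list[str]] = None) -> PartsLibrary:
    """Deterministic synthetic parts for all IEP types."""
    from .hits import IEP_TYPES

    types = list(types or [t for t in IEP_TYPES if t != "unclassified"])
    rng = np.random.default_rng(_PARTS_SEED)
    motif_sets, iep_peps, motif_spans, rt_spans = {}, {}, {}, {}
    rt_queries, rt_variants = {}, {}
    for t in types:
        motifs = [_rand_pep(rng, int(rng.integers(10, 51))) for _ in range(N_MOTIFS)]
        motif_sets[t] = MotifSet(iep_type=t, motifs=motifs)
        parts = [_rand_pep(rng, _PAD_AA)]
        spans = []
        pos = _PAD_AA
        for i, m in enumerate(motifs):
            parts.append(m)
            spans.append((pos, pos + len(m)))
            pos += len(m)
            if i < N_MOTIFS - 1:
                parts.append(_rand_pep(rng, _LINKER_AA))
                pos += _LINKER_AA
        parts.append(_rand_pep(rng, _PAD_AA))
        pep = "".join(parts)
        iep_peps[t] = pep
        motif_spans[t] = spans
        rt_spans[t] = (spans[_RT_MOTIF_LO][0], spans[_RT_MOTIF_HI][1])
        q = pep[rt_spans[t][0] : rt_spans[t][1]]
        rt_queries[t] = q
        rt_variants[t] = [q] + [_mutate_pep(q, 0.05, rng) for _ in range(4)]
    dvvi = _rand_nt(rng, DVVI_LEN)
    d_motifs = {f"D{i}": _rand_nt(rng, D_MOTIF_LEN) for i in range(1, 5)}
    five_aln, five_cons = {}, {}
    for key in sorted(set(PROFILE_FOR_TYPE.values())):
        cons = _rand_nt(rng, FIVE_PRIME_LEN)
        five_cons[key] = cons
        five_aln[key] = [cons] + [_mutate_nt(cons, 0.06, rng) for _ in range(7)]
    return PartsLibrary(
        motif_sets=motif_sets,
        iep_peptides=iep_peps,
        motif_aa_spans=motif_spans,
        rt_aa_span=rt_spans,
        rt_queries=rt_queries,
        rt_variants=rt_variants,
        dvvi_motif=dvvi,
        d_motifs=d_motifs,
        five_prime_alignments=five_aln,
        five_prime_consensus=five_cons,
    )


# ---------------------------------------------------------------------------
# Background genome
# ---------------------------------------------------------------------------


def generate_genome(
    length: int,
    gc: float = 0.5,
    skew_amplitude: float = 0.0,
    ori: int = 0,
    seed: int = 0,
    replicon_id: str = "synth1",
) -> GenomeRecord:
    """i.i.d. background with a two-replichore G/C imbalance.

    On the arc ori -> ter (ascending coordinates) the top strand carries a
    G excess of +skew_amplitude, on the other arc -skew_amplitude (so the
    windowed skew flips sign at ori and ter).  Deterministic per seed.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0,1)")
    if abs(skew_amplitude) > 1:
        raise ValueError("|skew_amplitude| must be <= 1")
    rng = np.random.default_rng(seed)
    half = length // 2
    at = 1.0 - gc

    def block(n: int, s: float) -> np.ndarray:
        p = [at / 2, gc / 2 * (1 - s), gc / 2 * (1 + s), at / 2]  # A C G T
        return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)

    rep1 = block(half, skew_amplitude)
    rep2 = block(length - half, -skew_amplitude)
    arr = np.concatenate([rep1, rep2])
    arr = np.roll(arr, ori)  # replichore boundary lands on ori
    return GenomeRecord(
        replicon_id=replicon_id, sequence=arr.tobytes().decode("ascii"), topology="circular"
    )


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


@dataclass
class PlantSpec:
    kind: str  # iep_intron | orfless_intron | decoy_rt | decoy_dvvi | decoy_d1_opposite | terminator
    position: int
    strand: str = "+"
    iep_type: str = "C"
    interruptions: int = 0
    deleted_motifs: int = 0
    gap_rt_to_dvvi: int = 900
    terminator_offset: Optional[int] = None  # distance term 3' end -> intron 5' end
    terminator_shape: str = "L"

    def __post_init__(self) -> None:
        if self.gap_rt_to_dvvi < 0:
            raise ValueError("gap must be >= 0")
        if not 0 <= self.deleted_motifs <= N_MOTIFS:
            raise ValueError("deleted_motifs outside [0,15]")


@dataclass
class TruthEntry:
    kind: str
    replicon_id: str
    strand: str
    segment: tuple[int, int]
    iep_type: Optional[str] = None
    gap: Optional[int] = None
    rt: Optional[tuple[int, int]] = None
    dvvi: Optional[tuple[int, int]] = None
    dvvi_bits: float = 40.0
    d1_4: list = field(default_factory=list)  # (kind, interval, strand)
    orf: Optional[tuple[int, int]] = None
    five_prime: Optional[int] = None
    expected_status: Optional[str] = None
    terminator: Optional[TerminatorRecord] = None

    def expected_category(self, cfg: AssemblyConfig = AssemblyConfig()) -> Optional[str]:
        """Expected call category under a given assembly config, or None."""
        if self.kind == "iep_intron":
            return "iep_containing" if self.gap <= cfg.max_gap else None
        if self.kind == "orfless_intron":
            return "orf_less" if self.gap <= cfg.max_gap else None
        if self.kind == "decoy_rt":
            return "iep_containing" if self.gap <= cfg.max_gap else None
        return None


@dataclass
class TruthTable:
    entries: list[TruthEntry]

    def expected_calls(self, cfg: AssemblyConfig = AssemblyConfig()):
        return [e for e in self.entries if e.expected_category(cfg) is not None]

    def terminators(self) -> list[TerminatorRecord]:
        return [e.terminator for e in self.entries if e.terminator is not None]

    def to_domain_hits(self) -> list[DomainHit]:
        """The hit rows an external search would have produced."""
        hits = []
        for e in self.entries:
            if e.rt is not None:
                hits.append(
                    DomainHit(
                        replicon_id=e.replicon_id,
                        kind="RT",
                        start=e.rt[0],
                        end=e.rt[1],
                        strand=e.strand,
                        bit_score=250.0,
                        evalue=1e-80,
                        query_id=f"RT_{e.iep_type}",
                        query_coverage=1.0,
                        source="alignment",
                    )
                )
            if e.dvvi is not None:
                hits.append(
                    DomainHit(
                        replicon_id=e.replicon_id,
                        kind="DV_VI",
                        start=e.dvvi[0],
                        end=e.dvvi[1],
                        strand=e.strand,
                        bit_score=e.dvvi_bits,
                        evalue=1e-9,
                        query_id="DVVI",
                        query_coverage=1.0,
                        source="cm",
                    )
                )
            for kind, iv, strand in e.d1_4:
                hits.append(
                    DomainHit(
                        replicon_id=e.replicon_id,
                        kind=kind,
                        start=iv[0],
                        end=iv[1],
                        strand=strand,
                        bit_score=30.0,
                        evalue=1e-5,
                        query_id=kind,
                        query_coverage=1.0,
                        source="cm",
                    )
                )
        return hits


def _fwd(iv: tuple[int, int], p: int, seg_len: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return (p + iv[0], p + iv[1])
    return (p + seg_len - iv[1], p + seg_len - iv[0])


def _fwd_base(off: int, p: int, seg_len: int, strand: str) -> int:
    return p + off if strand == "+" else p + seg_len - 1 - off


def _terminator_part(shape: str, rng: np.random.Generator) -> tuple[str, int, int, int]:
    """Stem-loop plus 10-nt tail; returns (seq, stem_start, stem_end, term_3prime) offsets."""
    arm = _rand_nt(rng, STEM_ARM)
    loop = _rand_nt(rng, STEM_LOOP)
    if shape == "L":
        tail = "TTTT" + "".join("AGC"[i] for i in rng.integers(0, 3, TAIL_LEN - 4))
    else:
        tail = "".join("AGC"[i] for i in rng.integers(0, 3, TAIL_LEN))
    seq = arm + loop + revcomp(arm) + tail
    stem_len = 2 * STEM_ARM + STEM_LOOP
    return seq, 0, stem_len - 1, len(seq) - 1


def _build_iep_segment(spec: PlantSpec, parts: PartsLibrary, rng: np.random.Generator):
    t = spec.iep_type
    pep = parts.iep_peptides[t]
    spans = parts.motif_aa_spans[t]
    rt_lo, rt_hi = parts.rt_aa_span[t]

    keep = [True] * len(pep)
    if spec.deleted_motifs:
        if spec.deleted_motifs > len(_DELETABLE):
            raise ValueError("cannot delete more than 8 motifs without destroying the RT domain")
        for mi in _DELETABLE[: spec.deleted_motifs]:
            a, b = spans[mi]
            for i in range(a, b):
                keep[i] = False
    new_pos = np.cumsum(keep) - 1  # old aa index -> new aa index (where kept)
    pep2 = "".join(c for c, k in zip(pep, keep) if k)
    rt2 = (int(new_pos[rt_lo]), int(new_pos[rt_hi - 1]) + 1)

    codons = [_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in pep2]
    if spec.interruptions:
        # replace inter-motif linker residues upstream of the RT domain with
        # stop codons (never the N-terminal pad: a local alignment must keep
        # flanking motif signal on both sides of every stop)
        in_motif = [False] * len(pep)
        for a, b in spans:
            for i in range(a, b):
                in_motif[i] = True
        old_of_new = [i for i, k in enumerate(keep) if k]
        first_motif_end = next(
            int(new_pos[b - 1]) + 1 for a, b in spans if keep[a] and keep[b - 1]
        )
        linker_pool = [
            i2
            for i2 in range(first_motif_end, rt2[0])
            if not in_motif[old_of_new[i2]]
        ]
        if len(linker_pool) < spec.interruptions:
            raise ValueError("not enough linker positions for requested interruptions")
        for i in rng.choice(linker_pool, size=spec.interruptions, replace=False):
            codons[i] = "TAA"

    orf_nt = "ATG" + "".join(codons) + "TAA"
    rt_nt = (3 * (1 + rt2[0]), 3 * (1 + rt2[1]))  # within the ORF
    tail_after_rt = len(orf_nt) - rt_nt[1]
    if spec.gap_rt_to_dvvi < tail_after_rt:
        raise ValueError(
            f"gap_rt_to_dvvi={spec.gap_rt_to_dvvi} shorter than the ORF tail ({tail_after_rt} nt)"
        )

    key = PROFILE_FOR_TYPE.get(t)
    five = parts.five_prime_consensus[key] if key else _rand_nt(rng, FIVE_PRIME_LEN)
    # in-frame stop just before the start codon pins the ORF start: upstream
    # intron RNA is non-coding, so the reading frame must not leak into it
    seg = five + _rand_nt(rng, SPACER_5P - 3) + "TAA"
    orf_off = len(seg)
    seg += orf_nt
    seg += _rand_nt(rng, spec.gap_rt_to_dvvi - tail_after_rt)
    dvvi_off = len(seg)
    seg += parts.dvvi_motif + _rand_nt(rng, TAIL_LEN)

    if spec.interruptions:
        status = "interrupted"
    elif spec.deleted_motifs >= 5:
        status = "short_orf"
    else:
        status = "canonical"
    offsets = {
        "five_prime": 0,
        "orf": (orf_off, orf_off + len(orf_nt)),
        "rt": (orf_off + rt_nt[0], orf_off + rt_nt[1]),
        "dvvi": (dvvi_off, dvvi_off + DVVI_LEN),
    }
    return seg, offsets, status


def plant(
    genome: GenomeRecord,
    specs: list[PlantSpec],
    parts: PartsLibrary,
    seed: int = 0,
) -> tuple[GenomeRecord, TruthTable]:
    """Edit planted elements into a genome and record the truth.

    Segments are built in intron orientation, reverse-complemented for minus
    strand plants, and spliced over the background in place (genome length
    is preserved).  Overlapping plants raise.
    """
    rng = np.random.default_rng(seed)
    seq = list(genome.sequence)
    occupied: list[tuple[int, int]] = []
    entries: list[TruthEntry] = []
    for spec in specs:
        srng = np.random.default_rng(rng.integers(2**31))
        term_part = None
        if spec.kind == "iep_intron":
            seg, off, status = _build_iep_segment(spec, parts, srng)
            if spec.terminator_offset is not None:
                if spec.terminator_offset < 1:
                    raise ValueError("terminator_offset must be >= 1")
                tseq, s0, s1, t3 = _terminator_part(spec.terminator_shape, srng)
                term_part = (tseq, s0, s1, t3)
                shift = len(tseq) + spec.terminator_offset - 1
                seg = tseq + _rand_nt(srng, spec.terminator_offset - 1) + seg
                off = {
                    k: (v + shift if isinstance(v, int) else (v[0] + shift, v[1] + shift))
                    for k, v in off.items()
                }
        elif spec.kind == "orfless_intron":
            d1 = parts.d_motifs["D1"]
            seg = d1 + _rand_nt(srng, spec.gap_rt_to_dvvi)
            dvvi_off = len(seg)
            seg += parts.dvvi_motif + _rand_nt(srng, TAIL_LEN)
            off = {"d1": (0, len(d1)), "dvvi": (dvvi_off, dvvi_off + DVVI_LEN)}
            status = None
        elif spec.kind == "decoy_rt":
            q = parts.rt_queries[spec.iep_type]
            orf = "ATG" + reverse_translate(q, srng) + "TAA"
            if spec.gap_rt_to_dvvi < 3:
                raise ValueError("decoy_rt gap must cover the stop codon (>= 3)")
            seg = orf + _rand_nt(srng, spec.gap_rt_to_dvvi - 3)
            dvvi_off = len(seg)
            seg += parts.dvvi_motif + _rand_nt(srng, TAIL_LEN)
            off = {"rt": (3, 3 + 3 * len(q)), "dvvi": (dvvi_off, dvvi_off + DVVI_LEN)}
            status = None
        elif spec.kind == "decoy_dvvi":
            seg = _mutate_nt(parts.dvvi_motif, 0.3, srng) + _rand_nt(srng, TAIL_LEN)
            off = {"dvvi": (0, DVVI_LEN)}
            status = None
        elif spec.kind == "decoy_d1_opposite":
            seg = revcomp(parts.d_motifs["D1"]) + _rand_nt(srng, spec.gap_rt_to_dvvi)
            dvvi_off = len(seg)
            seg += parts.dvvi_motif + _rand_nt(srng, TAIL_LEN)
            off = {"d1_opp": (0, D_MOTIF_LEN), "dvvi": (dvvi_off, dvvi_off + DVVI_LEN)}
            status = None
        elif spec.kind == "terminator":
            tseq, s0, s1, t3 = _terminator_part(spec.terminator_shape, srng)
            term_part = (tseq, s0, s1, t3)
            seg = tseq
            off = {}
            status = None
        else:
            raise ValueError(f"unknown plant kind {spec.kind!r}")

        p, S = spec.position, len(seg)
        if p < 0 or p + S > genome.length:
            raise ValueError(f"plant at {p} does not fit the genome")
        for a, b in occupied:
            if p < b and a < p + S:
                raise ValueError(f"plants overlap at [{p},{p + S})")
        occupied.append((p, p + S))
        placed = seg if spec.strand == "+" else revcomp(seg)
        seq[p : p + S] = placed

        entry = TruthEntry(
            kind=spec.kind,
            replicon_id=genome.replicon_id,
            strand=spec.strand,
            segment=(p, p + S),
            iep_type=spec.iep_type if spec.kind in ("iep_intron", "decoy_rt") else None,
            gap=spec.gap_rt_to_dvvi if spec.kind in ("iep_intron", "orfless_intron", "decoy_rt") else None,
            expected_status=status,
        )
        if "rt" in off:
            entry.rt = _fwd(off["rt"], p, S, spec.strand)
        if "dvvi" in off:
            entry.dvvi = _fwd(off["dvvi"], p, S, spec.strand)
            if spec.kind == "decoy_dvvi":
                entry.dvvi_bits = 23.9
        if "orf" in off:
            entry.orf = _fwd(off["orf"], p, S, spec.strand)
        if "five_prime" in off:
            entry.five_prime = _fwd_base(off["five_prime"], p, S, spec.strand)
        if "d1" in off:
            entry.d1_4 = [("D1", _fwd(off["d1"], p, S, spec.strand), spec.strand)]
        if "d1_opp" in off:
            opp = "-" if spec.strand == "+" else "+"
            entry.d1_4 = [("D1", _fwd(off["d1_opp"], p, S, spec.strand), opp)]
        if term_part is not None:
            tseq, s0, s1, t3 = term_part
            if spec.strand == "+":
                entry.terminator = TerminatorRecord(
                    genome.replicon_id, "+", p + s0, p + s1, p + t3,
                    shape=spec.terminator_shape,
                )
            else:
                entry.terminator = TerminatorRecord(
                    genome.replicon_id,
                    "-",
                    p + S - 1 - s1,
                    p + S - 1 - s0,
                    p + S - 1 - t3,
                    shape=spec.terminator_shape,
                )
        entries.append(entry)

    out = GenomeRecord(
        replicon_id=genome.replicon_id,
        sequence="".join(seq),
        topology=genome.topology,
        organism_label=genome.organism_label,
        assembly_id=genome.assembly_id,
    )
    return out, TruthTable(entries=entries)


# ---------------------------------------------------------------------------
# Hit-table files in the dialects hit_ingest reads
# ---------------------------------------------------------------------------


def write_hit_tables(truth: TruthTable, parts: PartsLibrary, prefix: str) -> dict[str, str]:
    """Write RT (protein tabular) + DV/VI and D1-4 (tblout) hit files.

    Returns {"rt": path, "dvvi": path, "d1_4": path}.
    """
    meta = parts.rt_query_meta()
    rt_path, dvvi_path, d_path = (f"{prefix}.rt.tsv", f"{prefix}.dvvi.tblout", f"{prefix}.d14.tblout")
    with open(rt_path, "w") as fh:
        for h in truth.to_domain_hits():
            if h.kind != "RT":
                continue
            qlen = meta[h.query_id]["length"]
            s1, s2 = (h.start + 1, h.end) if h.strand == "+" else (h.end, h.start + 1)
            fh.write(
                f"{h.query_id}\t{h.replicon_id}\t100.0\t{qlen}\t0\t0\t1\t{qlen}\t{s1}\t{s2}"
                f"\t{h.evalue:g}\t{h.bit_score:g}\n"
            )
    with open(dvvi_path, "w") as fh, open(d_path, "w") as fd:
        for h in truth.to_domain_hits():
            if h.kind == "RT":
                continue
            s1, s2 = (h.start + 1, h.end) if h.strand == "+" else (h.end, h.start + 1)
            qlen = DVVI_LEN if h.kind == "DV_VI" else D_MOTIF_LEN
            row = (
                f"{h.replicon_id}\t-\t{h.query_id}\t-\tcm\t1\t{qlen}\t{s1}\t{s2}\t{h.strand}"
                f"\tno\t1\t0.5\t0.0\t{h.bit_score:g}\t{h.evalue:g}\t!\t-\n"
            )
            (fh if h.kind == "DV_VI" else fd).write(row)
    return {"rt": rt_path, "dvvi": dvvi_path, "d1_4": d_path}
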