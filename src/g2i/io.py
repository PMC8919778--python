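"""Genome and annotation I/O.

Reads replicon sequences from FASTA or GenBank, terminator tables from TSV,
and writes/reads intron calls as GFF3 or TSV.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open intervals on the forward
strand of the replicon, with strand carried separately.  Every emitted file
uses 1-based inclusive coordinates (GFF3 convention); converting out and back
in is the identity.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO

log = logging.getLogger("g2i")

_VALID = set("ACGTN")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """One replicon: sequence plus topology and identifiers."""

    replicon_id: str
    sequence: str
    topology: str = "circular"
    organism_label: Optional[str] = None
    assembly_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"bad topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class TerminatorRecord:
    """A rho-independent terminator: stem-loop extent plus 3' end.

    Coordinates are 0-based positions of single bases (stem boundaries and
    the terminator 3'-terminal base).  On the + strand term_3prime lies at or
    downstream of stem_end; mirrored on the - strand.
    """

    replicon_id: str
    strand: str
    stem_start: int
    stem_end: int
    term_3prime: int
    shape: str = "unknown"  # L, I or unknown


def _clean_seq(raw: str, record_id: str) -> str:
    seq = raw.upper()
    if not set(seq) <= _VALID:
        n_bad = sum(c not in _VALID for c in seq)
        log.warning("record %s: %d non-ACGTN characters mapped to N", record_id, n_bad)
        seq = "".join(c if c in _VALID else "N" for c in seq)
    return seq


def load_genomes(path: str, topology_default: str = "circular") -> list[GenomeRecord]:
    """Read replicons from a FASTA or GenBank file.

    Lowercase input is uppercased; any character outside A/C/G/T/N is mapped
    to N with a warning.  The format is chosen from the file extension
    (.gb/.gbk/.gbff/.genbank -> GenBank, otherwise FASTA).
    """
    ext = os.path.splitext(path)[1].lower()
    fmt = "genbank" if ext in (".gb", ".gbk", ".gbff", ".genbank") else "fasta"
    try:
        records = list(SeqIO.parse(path, fmt))
    except Exception as exc:  # pragma: no cover - Bio error text varies
        raise ValueError(f"could not parse {path!r} as {fmt}: {exc}") from exc
    if not records:
        raise ValueError(f"no sequence records in {path!r}")
    out = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate replicon_id {rec.id!r} in {path!r}")
        seen.add(rec.id)
        organism = None
        topology = topology_default
        if fmt == "genbank":
            organism = rec.annotations.get("organism")
            topology = rec.annotations.get("topology", topology_default)
            if topology not in ("circular", "linear"):
                topology = topology_default
        out.append(
            GenomeRecord(
                replicon_id=rec.id,
                sequence=_clean_seq(str(rec.seq), rec.id),
                topology=topology,
                organism_label=organism,
            )
        )
    return out


def load_terminators(
    path: str, genomes: Optional[dict[str, GenomeRecord]] = None
) -> list[TerminatorRecord]:
    """Read a tab-delimited terminator table.

    Expected columns (header row required): replicon_id, strand, stem_start,
    stem_end, term_3prime and optionally shape.  Input coordinates are
    1-based positions and converted to 0-based.  Rows violating the stem
    invariant, or lying outside a known replicon, are skipped with a warning.
    """
    out: list[TerminatorRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("replicon_id", "strand", "stem_start", "stem_end", "term_3prime"):
            if col not in idx:
                raise ValueError(f"terminator table missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            rid = f[idx["replicon_id"]]
            strand = f[idx["strand"]]
            stem_start = int(f[idx["stem_start"]]) - 1
            stem_end = int(f[idx["stem_end"]]) - 1
            term3 = int(f[idx["term_3prime"]]) - 1
            shape = f[idx["shape"]] if "shape" in idx and len(f) > idx["shape"] else "unknown"
            if shape not in ("L", "I"):
                shape = "unknown"
            if stem_start >= stem_end:
                log.warning("terminator line %d: stem_end <= stem_start, skipped", lineno)
                continue
            if genomes is not None:
                g = genomes.get(rid)
                if g is None or not (0 <= stem_start and max(stem_end, term3) < g.length) or term3 < 0:
                    log.warning("terminator line %d: outside replicon %s, skipped", lineno, rid)
                    continue
            out.append(TerminatorRecord(rid, strand, stem_start, stem_end, term3, shape))
    return out


# ---------------------------------------------------------------------------
# Intron-call export / import
# ---------------------------------------------------------------------------

_GFF_SOURCE = "g2i"
_GFF_TYPE = "mobile_genetic_element"

_TSV_COLUMNS = [
    "call_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "category",
    "iep_type",
    "iep_status",
    "five_prime",
]


def _call_rows(calls) -> Iterable[dict]:
    for i, c in enumerate(calls):
        yield {
            "call_id": getattr(c, "call_id", None) or f"g2i_{i + 1:04d}",
            "replicon_id": c.replicon_id,
            "start": c.span[0] + 1,  # 1-based inclusive
            "end": c.span[1],
            "strand": c.strand,
            "category": c.category,
            "iep_type": c.iep_type or ".",
            "iep_status": c.iep_status or ".",
            "five_prime": c.five_prime + 1 if c.five_prime is not None else ".",
        }


def export_calls(calls, path: str, fmt: str = "gff3", known_replicons: Optional[set] = None) -> None:
    """Write intron calls as GFF3 or TSV (1-based inclusive coordinates)."""
    if known_replicons is not None:
        for c in calls:
            if c.replicon_id not in known_replicons:
                raise ValueError(f"call references unknown replicon {c.replicon_id!r}")
    fmt = fmt.lower()
    with open(path, "w") as fh:
        if fmt == "gff3":
            fh.write("##gff-version 3\n")
            for row in _call_rows(calls):
                attrs = ";".join(
                    f"{k}={row[k]}"
                    for k in ("call_id", "category", "iep_type", "iep_status", "five_prime")
                )
                fh.write(
                    "\t".join(
                        [
                            row["replicon_id"],
                            _GFF_SOURCE,
                            _GFF_TYPE,
                            str(row["start"]),
                            str(row["end"]),
                            ".",
                            row["strand"],
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
        elif fmt == "tsv":
            fh.write("\t".join(_TSV_COLUMNS) + "\n")
            for row in _call_rows(calls):
                fh.write("\t".join(str(row[k]) for k in _TSV_COLUMNS) + "\n")
        else:
            raise ValueError(f"unknown export format {fmt!r}")


def import_calls(path: str, fmt: str = "gff3"):
    """Re-read exported calls (returns bare IntronCall objects without hits)."""
    from .assembly import IntronCall

    calls = []
    fmt = fmt.lower()
    with open(path) as fh:
        if fmt == "gff3":
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                calls.append(
                    IntronCall(
                        replicon_id=f[0],
                        strand=f[6],
                        category=attrs.get("category", "orf_less"),
                        span=(int(f[3]) - 1, int(f[4])),
                        iep_type=None if attrs.get("iep_type", ".") == "." else attrs["iep_type"],
                        iep_status=None if attrs.get("iep_status", ".") == "." else attrs["iep_status"],
                        five_prime=None if attrs.get("five_prime", ".") == "." else int(attrs["five_prime"]) - 1,
                        call_id=attrs.get("call_id"),
                    )
                )
        elif fmt == "tsv":
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                calls.append(
                    IntronCall(
                        replicon_id=row["replicon_id"],
                        strand=row["strand"],
                        category=row["category"],
                        span=(int(row["start"]) - 1, int(row["end"])),
                        iep_type=None if row["iep_type"] == "." else row["iep_type"],
                        iep_status=None if row["iep_status"] == "." else row["iep_status"],
                        five_prime=None if row["five_prime"] == "." else int(row["five_prime"]) - 1,
                        call_id=row["call_id"],
                    )
                )
        else:
            raise ValueError(f"unknown import format {fmt!r}")
    return calls
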