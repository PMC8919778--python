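"""Pipeline orchestration and per-genome summaries.

The full workflow is: load genomes -> gather domain-hit evidence (external
hit tables or the built-in scanner) -> filter per the evidence thresholds ->
assemble intron calls -> IEP extraction/classification -> 5'-end and
terminator context -> replication-strand and GC-skew statistics -> summary.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import context as ctx
from . import repgeo
from .assembly import AssemblyConfig, IntronCall, call_introns
from .hits import (
    DomainHit,
    FilterConfig,
    builtin_local_search,
    filter_and_type_rt_hits,
    filter_structural_hits,
    parse_hit_table,
)
from .iep import IEPRecord, MotifSet, analyze_iep
from .io import GenomeRecord, TerminatorRecord, export_calls, load_genomes, load_terminators

log = logging.getLogger("g2i")


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    calls: list[IntronCall]
    ieps: dict[str, IEPRecord] = field(default_factory=dict)  # call_id -> record
    term_context: list[dict] = field(default_factory=list)
    skew: dict[str, repgeo.SkewProfile] = field(default_factory=dict)
    gcsi: dict[str, float] = field(default_factory=dict)
    ib: Optional[repgeo.IBResult] = None
    filter_log: dict[str, int] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return summarize(self.calls, self.ieps, self.genomes, self.gcsi)


def filter_hits(
    raw_hits: list[DomainHit],
    cfg: FilterConfig = FilterConfig(),
    query_meta: Optional[dict] = None,
    counts: Optional[dict] = None,
) -> list[DomainHit]:
    """Apply the RT and structural filters, recording in/out counts."""
    rt_in = [h for h in raw_hits if h.kind == "RT"]
    st_in = [h for h in raw_hits if h.kind != "RT"]
    rt = filter_and_type_rt_hits(rt_in, cfg, query_meta=query_meta)
    st = filter_structural_hits(st_in, cfg)
    if counts is not None:
        counts.update(
            {
                "rt_hits_in": len(rt_in),
                "rt_hits_kept": len(rt),
                "structural_hits_in": len(st_in),
                "structural_hits_kept": len(st),
            }
        )
    return rt + st


def run_pipeline_objects(
    genomes: list[GenomeRecord],
    raw_hits: list[DomainHit],
    filter_cfg: FilterConfig = FilterConfig(),
    asm_cfg: AssemblyConfig = AssemblyConfig(),
    query_meta: Optional[dict] = None,
    references: Optional[dict[str, str]] = None,
    motif_sets: Optional[dict[str, MotifSet]] = None,
    profiles: Optional[dict[str, ctx.FivePrimeProfile]] = None,
    terminators: Optional[list[TerminatorRecord]] = None,
    ori: Optional[dict[str, int]] = None,
    skew_window: int = repgeo.SKEW_WINDOW,
    max_term_search: int = ctx.MAX_TERM_SEARCH,
) -> PipelineResult:
    """Run every stage on in-memory objects; inputs beyond hits are optional."""
    counts: dict[str, int] = {}
    hits = filter_hits(raw_hits, filter_cfg, query_meta=query_meta, counts=counts)
    calls: list[IntronCall] = []
    for g in genomes:
        calls.extend(call_introns(g, hits, asm_cfg))
    counts["calls"] = len(calls)
    by_replicon = {g.replicon_id: g for g in genomes}
    res = PipelineResult(genomes=genomes, calls=calls, filter_log=counts)

    if references is not None:
        for c in calls:
            if c.category != "iep_containing":
                continue
            rec = analyze_iep(c, by_replicon[c.replicon_id], references, motif_sets or {})
            c.iep_status = rec.status
            res.ieps[c.call_id] = rec

    if profiles is not None:
        for c in calls:
            if c.category != "iep_containing":
                continue
            rec = res.ieps.get(c.call_id)
            iep_start = rec.orf_genome_start if rec is not None else None
            c.five_prime = ctx.locate_5prime(
                c, by_replicon[c.replicon_id], profiles, iep_start=iep_start
            )
        if terminators is not None:
            for c in calls:
                if c.five_prime is None:
                    continue
                g = by_replicon[c.replicon_id]
                hit = ctx.terminator_distance(
                    c.five_prime, c.strand, terminators, max_term_search, c.replicon_id
                )
                if hit is None:
                    continue
                d, t = hit
                shape = t.shape if t.shape != "unknown" else ctx.classify_terminator_shape(t, g)
                res.term_context.append(
                    {
                        "call_id": c.call_id,
                        "iep_type": c.iep_type,
                        "distance": d,
                        "bin": ctx.bin_distance(d),
                        "shape": shape,
                    }
                )

    for g in genomes:
        res.skew[g.replicon_id] = repgeo.gc_skew_profile(g, skew_window)
        if g.length >= repgeo.GCSI_WINDOWS:
            res.gcsi[g.replicon_id], _, _ = repgeo.gcsi(g)

    if ori:
        classes = []
        for c in calls:
            o = ori.get(c.replicon_id)
            if o is None:
                continue
            model = repgeo.ReplicationModel(c.replicon_id, o, by_replicon[c.replicon_id].length)
            classes.append(repgeo.strand_class(c.span[0], c.strand, model))
        res.ib = repgeo.ib_score(classes)
    return res


def summarize(
    calls: list[IntronCall],
    ieps: dict[str, IEPRecord],
    genomes: list[GenomeRecord],
    gcsi: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Per-genome summary: call counts by IEP type and IEP status, GCSI.

    Genomes are grouped by assembly_id when present, else per replicon.
    A genome with no calls keeps its all-zero row.
    """
    from .hits import IEP_TYPES

    def key(g: GenomeRecord) -> str:
        return g.assembly_id or g.replicon_id

    rows = {}
    for g in genomes:
        k = key(g)
        if k not in rows:
            rows[k] = {
                "assembly": k,
                "genome_size": 0,
                "n_calls": 0,
                "orf_less": 0,
                "canonical": 0,
                "non_canonical": 0,
                "gcsi": np.nan,
                **{f"type_{t}": 0 for t in IEP_TYPES},
            }
        rows[k]["genome_size"] += g.length
        if gcsi and g.replicon_id in gcsi:
            prev = rows[k].get("_longest", -1)
            if g.length > prev:
                rows[k]["gcsi"] = gcsi[g.replicon_id]  # longest replicon represents the genome
                rows[k]["_longest"] = g.length
    by_replicon = {g.replicon_id: key(g) for g in genomes}
    for c in calls:
        r = rows[by_replicon[c.replicon_id]]
        r["n_calls"] += 1
        if c.category == "orf_less":
            r["orf_less"] += 1
        else:
            r[f"type_{c.iep_type or 'unclassified'}"] += 1
            rec = ieps.get(c.call_id)
            if rec is not None:
                if rec.status == "canonical":
                    r["canonical"] += 1
                else:
                    r["non_canonical"] += 1
    for r in rows.values():
        r.pop("_longest", None)
    df = pd.DataFrame(list(rows.values())).set_index("assembly").sort_index()
    return df


def regress_counts_vs_size(summary: pd.DataFrame) -> float:
    """Ordinary least squares R^2 of intron count on genome size."""
    if len(summary) < 3:
        raise ValueError("need at least 3 genomes")
    x = summary["genome_size"].to_numpy(dtype=float)
    y = summary["n_calls"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in genome size")
    if np.ptp(y) == 0:
        return 0.0
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# Config-file front end
# ---------------------------------------------------------------------------


def _load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config, outdir: str) -> PipelineResult:
    """File-level pipeline: config dict (or YAML/JSON path) -> output files.

    Writes calls.gff3, calls.tsv, ieps.tsv, context.tsv, skew.tsv,
    summary.tsv and counts.json under outdir.  Reruns with identical inputs
    produce byte-identical outputs.
    """
    if isinstance(config, (str, os.PathLike)):
        config = _load_config(os.fspath(config))
    os.makedirs(outdir, exist_ok=True)
    genomes = load_genomes(
        config["genomes"], topology_default=config.get("topology_default", "circular")
    )
    by_replicon = {g.replicon_id: g for g in genomes}

    query_meta = None
    if config.get("query_meta"):
        with open(config["query_meta"]) as fh:
            query_meta = json.load(fh)

    raw_hits: list[DomainHit] = []
    for spec in config.get("hits", []):
        raw_hits.extend(
            parse_hit_table(spec["path"], spec["dialect"], spec["kind"], query_meta=query_meta)
        )
    for spec in config.get("builtin_scan", []):
        from Bio import SeqIO

        queries = {r.id: str(r.seq).upper() for r in SeqIO.parse(spec["queries"], "fasta")}
        for g in genomes:
            raw_hits.extend(
                builtin_local_search(
                    g,
                    queries,
                    mode=spec.get("mode", "translated"),
                    score_min=spec.get("score_min", 50.0),
                    kind=spec["kind"],
                    query_meta=query_meta,
                )
            )

    filter_cfg = FilterConfig(**config.get("filters", {}))
    asm_cfg = AssemblyConfig(**config.get("assembly", {}))

    references = None
    if config.get("iep_references"):
        from Bio import SeqIO

        references = {r.id: str(r.seq).upper() for r in SeqIO.parse(config["iep_references"], "fasta")}
    motif_sets = None
    if config.get("motif_sets"):
        with open(config["motif_sets"]) as fh:
            motif_sets = {
                t: MotifSet(iep_type=t, motifs=m) for t, m in json.load(fh).items()
            }
    profiles = None
    if config.get("five_prime_alignments"):
        from Bio import SeqIO

        profiles = {}
        for key, path in config["five_prime_alignments"].items():
            aln = [str(r.seq).upper() for r in SeqIO.parse(path, "fasta")]
            profiles[key] = ctx.build_profile(aln, key)
    terminators = None
    if config.get("terminators"):
        terminators = load_terminators(config["terminators"], by_replicon)
    ori = None
    if config.get("ori_table"):
        ori = repgeo.load_ori_table(config["ori_table"])

    res = run_pipeline_objects(
        genomes,
        raw_hits,
        filter_cfg=filter_cfg,
        asm_cfg=asm_cfg,
        query_meta=query_meta,
        references=references,
        motif_sets=motif_sets,
        profiles=profiles,
        terminators=terminators,
        ori=ori,
        skew_window=config.get("skew_window", repgeo.SKEW_WINDOW),
        max_term_search=config.get("max_term_search", ctx.MAX_TERM_SEARCH),
    )

    known = set(by_replicon)
    export_calls(res.calls, os.path.join(outdir, "calls.gff3"), "gff3", known)
    export_calls(res.calls, os.path.join(outdir, "calls.tsv"), "tsv", known)
    with open(os.path.join(outdir, "ieps.tsv"), "w") as fh:
        fh.write("call_id\tstatus\tn_missing_motifs\tn_internal_stops\taa_len\n")
        for cid in sorted(res.ieps):
            r = res.ieps[cid]
            fh.write(
                f"{cid}\t{r.status}\t{r.n_missing_motifs}\t{len(r.internal_stop_positions)}\t{len(r.aa_seq)}\n"
            )
    with open(os.path.join(outdir, "context.tsv"), "w") as fh:
        fh.write("call_id\tiep_type\tdistance\tbin\tshape\n")
        for row in sorted(res.term_context, key=lambda r: r["call_id"]):
            fh.write(f"{row['call_id']}\t{row['iep_type']}\t{row['distance']}\t{row['bin']}\t{row['shape']}\n")
    with open(os.path.join(outdir, "skew.tsv"), "w") as fh:
        fh.write("replicon_id\twindow\tindex\tskew\tcumulative\n")
        for rid in sorted(res.skew):
            p = res.skew[rid]
            for i, (s, c) in enumerate(zip(p.skew, p.cumulative)):
                fh.write(f"{rid}\t{p.window}\t{i}\t{s:.6f}\t{c:.6f}\n")
    res.summary().to_csv(os.path.join(outdir, "summary.tsv"), sep="\t")
    payload = dict(res.filter_log)
    if res.ib is not None:
        payload["ib_score"] = None if math.isnan(res.ib.ib_score) else (
            "inf" if math.isinf(res.ib.ib_score) else res.ib.ib_score
        )
        payload["ib_category"] = res.ib.category
    with open(os.path.join(outdir, "counts.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return res
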