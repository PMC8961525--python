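"""End-to-end pipeline: filter -> cluster -> collapse -> classify ->
events -> differential splicing -> expression -> integration.

Every stage writes a plain-text artifact (GTF/BED/TSV/JSON) that its own
module can read back, so stages are independently re-runnable.  The run
summary mirrors the census a study of this kind reports: isoform category
counts, per-type AS event counts, and DAS/DEG/DE-DAS/DE-DAS-TF tallies
with directions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate, das as das_mod, events as events_mod, expression
from .annotation_io import filter_flnc, read_annotation, write_annotation
from .model import GenomeAnnotation, JunctionTable, Transcript

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths, thresholds, and condition design for one run."""

    out_dir: str = "isoscan_out"
    reference_path: str | None = None
    reads_path: str | None = None
    reads_format: str = "gtf"
    junctions_path: str | None = None
    retention_path: str | None = None
    gene_counts_path: str | None = None
    tf_list_path: str | None = None
    condition_map: dict[str, str] = field(default_factory=dict)
    condition_a: str = "A"
    condition_b: str = "B"
    min_overlap: float = 0.20
    flnc_min_len: int = 50
    flnc_max_len: int = 15000
    delta_ei_threshold: float = 0.05
    fdr_threshold: float = 0.05
    log2fc_threshold: float = 1.0
    fpkm_expressed: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("min_overlap", "delta_ei_threshold", "fdr_threshold",
                     "log2fc_threshold", "fpkm_expressed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _split_reads(reads: list[Transcript]) -> tuple[list[Transcript], list[Transcript]]:
    """Separate single-segment reads from split-aligned (fusion candidate) reads."""
    by_read: dict[str, list[Transcript]] = {}
    for t in reads:
        by_read.setdefault(t.read_id or t.id, []).append(t)
    single, multi = [], []
    for rid in sorted(by_read):
        segs = by_read[rid]
        (multi if len(segs) > 1 else single).extend(segs)
    return single, multi


def annotate_reads(
    reads: list[Transcript],
    reference: GenomeAnnotation,
    junctions: JunctionTable,
    min_overlap: float = 0.20,
):
    """Cluster, collapse and classify reads; returns (loci, classifications, fusions).

    Split-aligned reads are screened for fusions first; single-segment
    reads go through loci clustering, redundancy collapse, and
    known/novel classification.
    """
    single, multi = _split_reads(reads)
    fusions = (
        annotate.detect_fusions(multi, reference, junctions, min_overlap) if multi else []
    )
    loci = annotate.cluster_loci(single, min_overlap)
    classifications: list[annotate.IsoformClassification] = []
    for locus in loci:
        collapsed = annotate.collapse_isoforms(locus, junctions, reference)
        locus.members = collapsed
        for iso in collapsed:
            cls = annotate.classify_isoform(iso, locus, reference, min_overlap)
            classifications.append(cls)
            if cls.partner_genes and cls.category in (
                annotate.CATEGORY_KNOWN, annotate.CATEGORY_NOVEL_ISOFORM
            ):
                locus.annotated_gene_ids.update(cls.partner_genes)
    return loci, classifications, fusions


def locus_gene_map(loci) -> dict[str, str]:
    """locus id -> representative annotated gene (smallest id wins ties)."""
    return {
        L.id: sorted(L.annotated_gene_ids)[0] for L in loci if L.annotated_gene_ids
    }


def union_exon_lengths(loci, reference: GenomeAnnotation) -> pd.Series:
    """Gene length for FPKM: union-exon length of collapsed isoforms,
    falling back to the reference structure for genes without long-read
    support."""
    gene_map = locus_gene_map(loci)
    per_gene_exons: dict[str, list[tuple[int, int]]] = {}
    for L in loci:
        gene = gene_map.get(L.id)
        if gene is None:
            continue
        for m in L.members:
            per_gene_exons.setdefault(gene, []).extend((e.start, e.end) for e in m.exons)
    lengths: dict[str, int] = {}
    for gid in reference.genes:
        ivs = per_gene_exons.get(gid)
        if not ivs:
            ivs = [(e.start, e.end) for t in reference.genes[gid] for e in t.exons]
        merged: list[list[int]] = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        lengths[gid] = sum(e - s for s, e in merged)
    return pd.Series(lengths)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline from the configured inputs.

    Returns the run summary (also written to ``summary.json``).  A stage
    failure raises :class:`StageError` naming the stage; artifacts written
    so far are renamed with a ``.partial`` suffix.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    try:
        stage = "read_inputs"
        if cfg.reference_path is None or cfg.reads_path is None:
            raise FileNotFoundError("reference_path and reads_path are required")
        reference = read_annotation(cfg.reference_path, format="gtf", source="reference")
        reads_ann = read_annotation(cfg.reads_path, format=cfg.reads_format, source="flnc_read")
        reads = reads_ann.transcripts

        stage = "filter"
        reads = filter_flnc(reads, cfg.flnc_min_len, cfg.flnc_max_len)

        stage = "cluster"
        if cfg.junctions_path is None:
            raise FileNotFoundError("junctions_path is required")
        junctions = JunctionTable.read_tsv(cfg.junctions_path)
        loci, classifications, fusions = annotate_reads(
            reads, reference, junctions, cfg.min_overlap
        )

        stage = "classify"
        cls_df = pd.DataFrame(
            [
                {
                    "transcript_id": c.transcript_id,
                    "category": c.category,
                    "matched_reference": c.matched_reference_transcript or "",
                    "partner_genes": ",".join(c.partner_genes),
                    "evidence": ";".join(c.evidence),
                }
                for c in classifications + fusions
            ]
        )
        emit("classification.tsv", lambda p: cls_df.to_csv(p, sep="\t", index=False))
        collapsed_ann = GenomeAnnotation(
            genes={L.id: L.members for L in loci if L.members},
            chrom_lengths=reference.chrom_lengths,
        )
        emit("isoforms.gtf", lambda p: write_annotation(collapsed_ann, p, "gtf"))
        emit("loci.bed", lambda p: _write_loci_bed(loci, p))

        stage = "events"
        all_events = []
        for L in loci:
            all_events.extend(events_mod.enumerate_events(L))
        emit("events.tsv", lambda p: _write_events_tsv(all_events, p))

        stage = "das"
        condition_map = cfg.condition_map or _infer_conditions(junctions)
        retention = (
            JunctionTable.read_tsv(cfg.retention_path) if cfg.retention_path else None
        )
        counts_list = das_mod.quantify_events(all_events, junctions, condition_map, retention)
        das_results = das_mod.run_das(
            counts_list, cfg.condition_a, cfg.condition_b,
            cfg.delta_ei_threshold, cfg.fdr_threshold,
        )
        das_df = das_mod.das_results_frame(das_results)
        emit("das.tsv", lambda p: das_df.to_csv(p, sep="\t", index=False))

        stage = "express"
        summary_expr = {}
        integration_df = pd.DataFrame()
        if cfg.gene_counts_path:
            gene_counts = pd.read_csv(cfg.gene_counts_path, sep="\t", index_col=0)
            lengths = union_exon_lengths(loci, reference)
            lengths = lengths.reindex(gene_counts.index).fillna(1000.0)
            fpkm = expression.compute_fpkm(gene_counts, lengths)
            expressed = expression.expressed_flags(fpkm, cfg.fpkm_expressed)
            deg_res = expression.deg_test(
                gene_counts, condition_map, cfg.condition_a, cfg.condition_b
            )
            deg_res = expression.call_degs(deg_res, cfg.log2fc_threshold, cfg.fdr_threshold)
            deg_res["is_expressed"] = expressed.reindex(deg_res.index).fillna(False)

            stage = "integrate"
            gene_map = locus_gene_map(loci)
            event_gene = {
                ev.id: gene_map[ev.locus_id] for ev in all_events if ev.locus_id in gene_map
            }
            tf_list = set()
            if cfg.tf_list_path:
                tf_list = {
                    line.strip()
                    for line in open(cfg.tf_list_path)
                    if line.strip() and not line.startswith("#")
                }
            integration_df = expression.integrate(deg_res, das_df, event_gene, tf_list)
            emit(
                "expression.tsv",
                lambda p: integration_df.to_csv(p, sep="\t", index_label="gene_id"),
            )
            summary_expr = _expression_summary(integration_df)

        stage = "summary"
        summary = _build_summary(loci, classifications, fusions, all_events, das_df)
        summary.update(summary_expr)
        summary["seed"] = cfg.seed
        emit(
            "summary.json",
            lambda p: p.write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n"),
        )
        return summary
    except Exception as exc:
        for p in written:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))
        raise StageError(stage, exc) from exc


def _infer_conditions(junctions: JunctionTable) -> dict[str, str]:
    # fall back to the sample naming convention of the simulator: <cond><rep>
    return {s: s.rstrip("0123456789") for s in junctions.samples}


def _write_loci_bed(loci, path) -> None:
    with open(path, "w") as fh:
        for L in loci:
            fh.write(
                f"{L.chrom}\t{L.span[0]}\t{L.span[1]}\t{L.id}\t{len(L.members)}\t{L.strand}\n"
            )


def _write_events_tsv(events, path) -> None:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.id,
                "locus": ev.locus_id,
                "type": ev.type,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "anchors": f"{ev.anchors[0]},{ev.anchors[1]}",
                "inclusion_junctions": ";".join(f"{d}-{a}" for d, a in sorted(ev.inclusion_junctions)),
                "exclusion_junctions": ";".join(f"{d}-{a}" for d, a in sorted(ev.exclusion_junctions)),
                "n_isoform_pairs": len(ev.isoform_pairs),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _build_summary(loci, classifications, fusions, all_events, das_df) -> dict:
    cat_counts: dict[str, int] = {}
    for c in classifications + fusions:
        cat_counts[c.category] = cat_counts.get(c.category, 0) + 1
    type_counts: dict[str, int] = {}
    for ev in all_events:
        type_counts[ev.type] = type_counts.get(ev.type, 0) + 1
    summary = {
        "n_loci": len(loci),
        "n_isoforms": sum(len(L.members) for L in loci),
        "isoform_categories": cat_counts,
        "as_event_types": type_counts,
        "n_events": len(all_events),
    }
    if not das_df.empty:
        das_events = das_df[das_df["is_das"]]
        summary["n_das_events"] = int(len(das_events))
        summary["n_das_increased"] = int((das_events["delta_EI"] > 0).sum())
        summary["n_das_decreased"] = int((das_events["delta_EI"] < 0).sum())
    else:
        summary["n_das_events"] = 0
        summary["n_das_increased"] = 0
        summary["n_das_decreased"] = 0
    return summary


def _expression_summary(df: pd.DataFrame) -> dict:
    up = df["is_deg"] & (df["log2fc"] > 0)
    down = df["is_deg"] & (df["log2fc"] < 0)
    return {
        "n_expressed": int(df["is_expressed"].sum()),
        "n_deg": int(df["is_deg"].sum()),
        "n_deg_up": int(up.sum()),
        "n_deg_down": int(down.sum()),
        "n_das_genes": int(df["is_das_gene"].sum()),
        "n_de_das": int(df["is_de_das"].sum()),
        "n_de_das_tf": int(df["is_de_das_tf"].sum()),
    }
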