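"""Readers and writers for transcript structure files (GTF, GFF3, BED12).

GTF/GFF3 parsing is delegated to :mod:`gffutils` (in-memory database);
this module only converts between file coordinates (1-based inclusive for
GTF/GFF3) and the package's internal 0-based half-open convention, and
groups exon records into :class:`~isoscan.model.Transcript` objects.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import gffutils
import pandas as pd

from .model import Exon, GenomeAnnotation, JunctionTable, Transcript, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "read_annotation",
    "write_annotation",
    "filter_flnc",
    "JunctionTable",
]


class ParseError(ValueError):
    """Raised for malformed annotation files; message names the line."""


def _precheck_gff(path: str | Path, n_columns: int = 9) -> None:
    """Light syntactic validation so errors can name a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path}: line {lineno}: expected >= 8 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise ParseError(f"{path}: line {lineno}: invalid coordinate range {start}-{end}")


def _read_gff(path: str | Path, dialect: str, source: str) -> GenomeAnnotation:
    _precheck_gff(path)
    with open(path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        logger.warning("%s: no records, returning empty annotation", path)
        return GenomeAnnotation()

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # exon -> transcript -> gene resolution differs between the dialects
    tx_exons: dict[str, list[Exon]] = {}
    tx_meta: dict[str, dict] = {}
    for ex in db.features_of_type("exon"):
        if dialect == "gtf":
            tids = ex.attributes.get("transcript_id", [])
            gids = ex.attributes.get("gene_id", [None])
        else:  # gff3
            tids = ex.attributes.get("Parent", [])
            gids = [None]
        if not tids:
            raise ParseError(f"{path}: exon without transcript assignment near {ex.seqid}:{ex.start}")
        for tid in tids:
            tx_exons.setdefault(tid, []).append(Exon(ex.start - 1, ex.end))
            meta = tx_meta.setdefault(tid, {"chrom": ex.seqid, "strand": ex.strand, "gene_id": gids[0]})
            if dialect == "gtf":
                if "support_count" in ex.attributes:
                    meta["support_count"] = int(ex.attributes["support_count"][0])
                if "read_id" in ex.attributes:
                    meta["read_id"] = ex.attributes["read_id"][0]

    if dialect == "gff3":
        for tid in tx_meta:
            try:
                parent_feature = db[tid]
                parents = parent_feature.attributes.get("Parent", [])
                tx_meta[tid]["gene_id"] = parents[0] if parents else tid
            except gffutils.FeatureNotFoundError:
                tx_meta[tid]["gene_id"] = tid

    genes: dict[str, list[Transcript]] = {}
    for tid, exons in tx_exons.items():
        meta = tx_meta[tid]
        gid = meta.get("gene_id") or tid
        t = Transcript(
            id=tid,
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=exons,
            source=source,
            support_count=meta.get("support_count", 1),
            gene_id=gid,
            read_id=meta.get("read_id"),
        )
        genes.setdefault(gid, []).append(t)
    chrom_lengths = _infer_chrom_lengths(genes)
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)


def _read_bed12(path: str | Path, source: str) -> GenomeAnnotation:
    genes: dict[str, list[Transcript]] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}: line {lineno}: BED12 requires 12 fields")
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                name = fields[3]
                score = fields[4]
                strand = fields[5]
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: malformed numeric field") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(f"{path}: line {lineno}: blockCount does not match block lists")
            exons = [Exon(chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)]
            support = int(score) if score.isdigit() and int(score) >= 1 else 1
            t = Transcript(
                id=name, chrom=chrom, strand=strand, exons=exons,
                source=source, support_count=support, gene_id=name,
            )
            genes.setdefault(name, []).append(t)
            n += 1
    if n == 0:
        logger.warning("%s: no records, returning empty annotation", path)
    g = GenomeAnnotation(genes=genes, chrom_lengths=_infer_chrom_lengths(genes))
    return g


def _infer_chrom_lengths(genes: dict[str, list[Transcript]]) -> dict[str, int]:
    lengths: dict[str, int] = {}
    for txs in genes.values():
        for t in txs:
            lengths[t.chrom] = max(lengths.get(t.chrom, 0), t.end)
    return lengths


def read_annotation(
    path: str | Path,
    format: str = "gtf",
    source: str = "reference",
    chrom_lengths: dict[str, int] | None = None,
) -> GenomeAnnotation:
    """Read transcript structures from a GTF, GFF3 or BED12 file.

    Coordinates are converted to 0-based half-open.  ``source`` is recorded
    on every transcript (``reference``, ``flnc_read`` or
    ``collapsed_isoform``).  When ``chrom_lengths`` is given, exons beyond a
    declared length raise :class:`~isoscan.model.ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("gtf", "gff3"):
        ann = _read_gff(path, format, source)
    elif format == "bed12":
        ann = _read_bed12(path, source)
    else:
        raise ValueError(f"unknown format {format!r}")
    if chrom_lengths is not None:
        for t in ann.transcripts:
            if t.chrom not in chrom_lengths:
                raise ValidationError(f"{t.id}: chrom {t.chrom} not in declared chrom lengths")
            if t.end > chrom_lengths[t.chrom]:
                raise ValidationError(
                    f"{t.id}: exon end {t.end} beyond chrom {t.chrom} length {chrom_lengths[t.chrom]}"
                )
        ann.chrom_lengths = dict(chrom_lengths)
    return ann


def _gtf_attr(t: Transcript) -> str:
    parts = [f'gene_id "{t.gene_id or t.id}"', f'transcript_id "{t.id}"']
    if t.support_count != 1:
        parts.append(f'support_count "{t.support_count}"')
    if t.read_id and t.read_id != t.id:
        parts.append(f'read_id "{t.read_id}"')
    return "; ".join(parts) + ";"


def write_annotation(ann: GenomeAnnotation, path: str | Path, format: str = "gtf") -> None:
    """Write an annotation as GTF or BED12 (round-trips with the reader)."""
    path = Path(path)
    txs = sorted(ann.transcripts, key=lambda t: (t.chrom, t.start, t.end, t.id))
    with open(path, "w") as fh:
        fh.write("# generated by isoscan\n")
        if format == "gtf":
            for t in txs:
                attr = _gtf_attr(t)
                fh.write(
                    f"{t.chrom}\tisoscan\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attr}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.chrom}\tisoscan\texon\t{e.start + 1}\t{e.end}\t.\t{t.strand}\t.\t{attr}\n"
                    )
        elif format == "bed12":
            for t in txs:
                sizes = ",".join(str(len(e)) for e in t.exons)
                starts = ",".join(str(e.start - t.start) for e in t.exons)
                fh.write(
                    "\t".join(
                        [
                            t.chrom, str(t.start), str(t.end), t.id,
                            str(t.support_count), t.strand, str(t.start), str(t.end),
                            "0", str(len(t.exons)), sizes, starts,
                        ]
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown format {format!r}")


def filter_flnc(
    reads: list[Transcript],
    min_len: int = 50,
    max_len: int = 15000,
    metadata: pd.DataFrame | None = None,
    min_passes: int = 3,
    min_accuracy: float = 0.99,
) -> list[Transcript]:
    """Length-filter full-length reads: keep ``min_len <= spliced length <= max_len``.

    Both bounds are inclusive.  ``metadata``, when given, is a per-read table
    with columns ``read_id``, ``passes``, ``accuracy``; reads failing
    ``passes >= min_passes`` or ``accuracy >= min_accuracy`` are also
    removed.  Those quantities are sequencing-run properties that alignment
    files do not carry, so without metadata that filter is skipped with a
    logged notice.
    """
    kept = [r for r in reads if min_len <= r.spliced_length <= max_len]
    n_len_removed = len(reads) - len(kept)
    if metadata is not None:
        meta = metadata.set_index("read_id")
        ok: list[Transcript] = []
        for r in kept:
            if r.read_id in meta.index:
                row = meta.loc[r.read_id]
                if row["passes"] < min_passes or row["accuracy"] < min_accuracy:
                    continue
            ok.append(r)
        logger.info("filter_flnc: removed %d by length, %d by passes/accuracy",
                    n_len_removed, len(kept) - len(ok))
        kept = ok
    else:
        logger.info("filter_flnc: removed %d by length; no passes/accuracy metadata, "
                    "quality filter skipped", n_len_removed)
    return kept
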