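"""Loci clustering, isoform collapse, and known/novel/fusion classification.

The unit of annotation is the *locus*: a cluster of same-strand,
structurally overlapping transcripts, built as the connected components of
a pairwise overlap relation (two structures belong together when their
genomic spans overlap by at least ``min_overlap`` of the shorter span, at
least one exon pair overlaps by the same fraction, and they are transcribed
in the same direction).

Within a locus, redundant and false-positive read structures are removed in
three ordered steps before any isoform is reported:

(i)   structures whose internal splice chain is identical to a longer
      member's are merged into it (read support summed);
(ii)  structures missing the 5' end — the splice chain is a strict
      3'-terminal suffix of a longer member's and the 5' terminus lies
      strictly inside it — are merged into that member;
(iii) structures supported by a single read are discarded, unless every one
      of their introns is annotated in the reference or supported by
      short-read junction evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import (
    GenomeAnnotation,
    JunctionTable,
    Transcript,
    ValidationError,
    fusion_breakpoint_key,
)

logger = logging.getLogger(__name__)

CATEGORY_KNOWN = "known"
CATEGORY_NOVEL_ISOFORM = "novel_isoform_annotated_locus"
CATEGORY_NOVEL_GENE = "novel_gene"
CATEGORY_FUSION = "fusion"


@dataclass
class Locus:
    """A cluster of same-strand overlapping transcripts."""

    id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    members: list[Transcript]
    annotated_gene_ids: set[str] = field(default_factory=set)


@dataclass
class IsoformClassification:
    transcript_id: str
    category: str
    matched_reference_transcript: str | None = None
    partner_genes: list[str] = field(default_factory=list)
    evidence: list[str] = field(default_factory=list)


def overlap_fraction(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Overlap length divided by the length of the shorter interval.

    Intervals are half-open; abutting intervals overlap by 0.
    """
    if a[1] <= a[0] or b[1] <= b[0]:
        raise ValidationError(f"zero-length span: {a} vs {b}")
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return ov / min(a[1] - a[0], b[1] - b[0])


def same_locus(a: Transcript, b: Transcript, min_overlap: float = 0.20) -> bool:
    """Pairwise rule for two structures belonging to the same locus."""
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if overlap_fraction(a.span, b.span) < min_overlap:
        return False
    for ea in a.exons:
        for eb in b.exons:
            if min(ea.end, eb.end) > max(ea.start, eb.start):
                if overlap_fraction((ea.start, ea.end), (eb.start, eb.end)) >= min_overlap:
                    return True
    return False


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_loci(reads: list[Transcript], min_overlap: float = 0.20) -> list[Locus]:
    """Group reads into loci: connected components of :func:`same_locus`.

    Single-linkage closure of the pairwise rule; deterministic output order
    by (chrom, start, strand).
    """
    uf = _UnionFind(len(reads))
    order = sorted(range(len(reads)), key=lambda i: (reads[i].chrom, reads[i].strand, reads[i].start))
    # sweep within (chrom, strand): only span-overlapping pairs can relate
    active: list[int] = []
    prev_key: tuple[str, str] | None = None
    for i in order:
        t = reads[i]
        key = (t.chrom, t.strand)
        if key != prev_key:
            active = []
            prev_key = key
        active = [j for j in active if reads[j].end > t.start]
        for j in active:
            if same_locus(t, reads[j], min_overlap):
                uf.union(i, j)
        active.append(i)

    groups: dict[int, list[Transcript]] = {}
    for i, t in enumerate(reads):
        groups.setdefault(uf.find(i), []).append(t)
    loci = []
    for members in groups.values():
        members = sorted(members, key=lambda t: (t.start, t.end, t.id))
        loci.append(
            Locus(
                id="",
                chrom=members[0].chrom,
                strand=members[0].strand,
                span=(min(t.start for t in members), max(t.end for t in members)),
                members=members,
            )
        )
    loci.sort(key=lambda L: (L.chrom, L.span[0], L.strand))
    for k, L in enumerate(loci):
        L.id = f"locus_{k + 1}"
    return loci


def _is_five_prime_fragment(m: Transcript, big: Transcript) -> bool:
    """True when ``m`` looks like ``big`` with a degraded 5' end."""
    cm, cb = m.splice_chain, big.splice_chain
    if len(cm) >= len(cb):
        return False
    if m.strand == "+":
        if cm and tuple(cb[-len(cm):]) != cm:
            return False
        if not (big.start < m.start < big.end):
            return False
        if not cm:  # single-exon remnant must sit over the 3'-terminal exon
            last = big.exons[-1]
            if min(m.end, last.end) <= max(m.start, last.start):
                return False
        return True
    else:
        if cm and tuple(cb[: len(cm)]) != cm:
            return False
        if not (big.start < m.end < big.end):
            return False
        if not cm:
            first = big.exons[0]
            if min(m.end, first.end) <= max(m.start, first.start):
                return False
        return True


def collapse_isoforms(
    locus: Locus,
    junction_support: JunctionTable,
    reference: GenomeAnnotation,
) -> list[Transcript]:
    """Remove redundant/false-positive structures from one locus.

    Applies the three rules in order (exact-chain merge, 5'-suffix merge,
    singleton filter with annotation/junction rescue) and returns one
    representative :class:`Transcript` per surviving isoform with summed
    ``support_count``.  Idempotent.
    """
    if not locus.members:
        return []
    ref_introns = set()
    for gid in reference.genes:
        ref_introns |= reference.introns_of(gid)

    # rule (i): merge identical internal splice chains into the longer one
    by_chain: dict[tuple[int, ...], list[Transcript]] = {}
    for m in locus.members:
        by_chain.setdefault(m.splice_chain, []).append(m)

    def rep_key(t: Transcript):
        # longest structure wins; among equals keep the more complete 5' end
        five = -t.start if t.strand == "+" else t.end
        return (t.spliced_length, five, t.id)

    survivors: list[Transcript] = []
    for chain, group in by_chain.items():
        rep = max(group, key=rep_key)
        support = sum(t.support_count for t in group)
        survivors.append(rep.with_(support_count=support, source="collapsed_isoform"))

    # rule (ii): merge 5'-degraded fragments into their parent
    survivors.sort(key=lambda t: len(t.splice_chain))
    merged: set[str] = set()
    for m in survivors:
        if m.id in merged:
            continue
        candidates = [
            b for b in survivors
            if b.id != m.id and b.id not in merged and _is_five_prime_fragment(m, b)
        ]
        if candidates:
            parent = max(candidates, key=lambda t: (len(t.splice_chain), t.spliced_length, t.id))
            parent.support_count += m.support_count
            merged.add(m.id)
    survivors = [t for t in survivors if t.id not in merged]

    # rule (iii): drop singletons unless every intron is annotated or supported
    kept: list[Transcript] = []
    n_dropped = 0
    for t in survivors:
        if t.support_count > 1:
            kept.append(t)
            continue
        rescued = all(
            (t.chrom, d, a, t.strand) in ref_introns
            or junction_support.supported(t.chrom, d, a, t.strand)
            for d, a in t.introns
        )
        if rescued:
            kept.append(t)
        else:
            n_dropped += 1
    if n_dropped:
        logger.info("%s: dropped %d unsupported singleton structure(s)", locus.id, n_dropped)
    kept.sort(key=lambda t: (t.start, t.end, t.id))
    return kept


def _gene_exonic_overlap(iso: Transcript, gene_txs: list[Transcript]) -> int:
    """Total bp of exonic intersection between iso and a gene's exon union."""
    points: set[tuple[int, int]] = set()
    for t in gene_txs:
        for e in t.exons:
            points.add((e.start, e.end))
    # merge gene exon union
    merged: list[list[int]] = []
    for s, e in sorted(points):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    total = 0
    for ei in iso.exons:
        for s, e in merged:
            total += max(0, min(ei.end, e) - max(ei.start, s))
    return total


def classify_isoform(
    iso: Transcript,
    locus: Locus,
    reference: GenomeAnnotation,
    min_overlap: float = 0.20,
) -> IsoformClassification:
    """Classify a collapsed isoform as known / novel isoform / novel gene.

    A structure belongs to a *novel gene* when no annotated gene passes the
    locus rule against it (overlap below threshold, or sufficient overlap
    but the opposite strand).  Over an annotated gene it is *known* when its
    full internal splice chain matches an annotated transcript (terminal
    exon boundaries are ignored — long-read termini are degraded), or it is
    a single-exon structure contained in a single-exon annotated transcript;
    otherwise it is a *novel isoform* of the annotated locus.
    """
    matching: list[str] = []
    opposite_strand_overlap = False
    for gid, txs in reference.genes.items():
        if txs[0].chrom != iso.chrom:
            continue
        if any(same_locus(iso, t, min_overlap) for t in txs):
            matching.append(gid)
        elif txs[0].strand != iso.strand:
            gchrom, gstrand, gs, ge = reference.gene_span(gid)
            if overlap_fraction(iso.span, (gs, ge)) >= min_overlap:
                opposite_strand_overlap = True

    if not matching:
        ev = (
            ["overlap >= threshold but opposite strand"]
            if opposite_strand_overlap
            else ["no annotated gene with sufficient overlap"]
        )
        return IsoformClassification(iso.id, CATEGORY_NOVEL_GENE, evidence=ev)

    best_gene = max(
        matching,
        key=lambda g: (_gene_exonic_overlap(iso, reference.genes[g]), g),
    )
    # an exact-chain match against ANY overlapping gene's transcript -> known
    for gid in matching:
        for t in reference.genes[gid]:
            if not iso.is_single_exon and not t.is_single_exon and iso.splice_chain == t.splice_chain:
                return IsoformClassification(
                    iso.id, CATEGORY_KNOWN, matched_reference_transcript=t.id,
                    partner_genes=[gid], evidence=["identical internal splice chain"],
                )
            if iso.is_single_exon and t.is_single_exon:
                if t.start <= iso.start and iso.end <= t.end:
                    return IsoformClassification(
                        iso.id, CATEGORY_KNOWN, matched_reference_transcript=t.id,
                        partner_genes=[gid], evidence=["single-exon contained in annotated single-exon"],
                    )

    evidence: list[str] = []
    best_txs = reference.genes[best_gene]
    annotated_sites = reference.splice_sites_of(best_gene)
    novel_sites = [s for s in iso.splice_chain if s not in annotated_sites]
    if novel_sites:
        evidence.append(f"{len(novel_sites)} splice site(s) absent from {best_gene}")
    best_single = all(t.is_single_exon for t in best_txs)
    if iso.is_single_exon != best_single:
        evidence.append("single-exon vs multi-exon mismatch with best reference match")
    if not evidence:
        evidence.append("novel arrangement of annotated splice sites")
    return IsoformClassification(
        iso.id, CATEGORY_NOVEL_ISOFORM, partner_genes=[best_gene], evidence=evidence
    )


def detect_fusions(
    reads: list[Transcript],
    reference: GenomeAnnotation,
    junction_support: JunctionTable,
    min_overlap: float = 0.20,
) -> list[IsoformClassification]:
    """Identify fusion transcripts among split-aligned reads.

    A read is a fusion when (i) its alignment segments overlap two or more
    distinct annotated gene loci, (ii) each segment overlaps its gene span
    by at least ``min_overlap`` of the shorter interval, and (iii) every
    breakpoint junction between consecutive segments is supported by
    short-read evidence in ``junction_support``.
    """
    if not reads:
        raise ValidationError("detect_fusions: empty segment list")
    by_read: dict[str, list[Transcript]] = {}
    for seg in reads:
        by_read.setdefault(seg.read_id or seg.id, []).append(seg)

    gene_spans = {gid: reference.gene_span(gid) for gid in reference.genes}
    results: list[IsoformClassification] = []
    for read_id in sorted(by_read):
        segments = sorted(by_read[read_id], key=lambda t: t.id)
        if len(segments) < 2:
            continue
        seg_genes: list[str | None] = []
        for seg in segments:
            best: tuple[int, str] | None = None
            for gid, (gchrom, gstrand, gs, ge) in gene_spans.items():
                if gchrom != seg.chrom:
                    continue
                if overlap_fraction(seg.span, (gs, ge)) < min_overlap:
                    continue
                ov = _gene_exonic_overlap(seg, reference.genes[gid])
                if best is None or (ov, gid) > best:
                    best = (ov, gid)
            seg_genes.append(best[1] if best else None)
        if any(g is None for g in seg_genes) or len(set(seg_genes)) < 2:
            continue
        supported = True
        for a, b in zip(segments, segments[1:]):
            pos5 = a.end if a.strand == "+" else a.start
            pos3 = b.start if b.strand == "+" else b.end
            chrom, donor, acceptor, strand = fusion_breakpoint_key(
                a.chrom, pos5, b.chrom, pos3, a.strand
            )
            if not junction_support.supported(chrom, donor, acceptor, strand):
                supported = False
                break
        if not supported:
            continue
        inter = len({s.chrom for s in segments}) > 1
        results.append(
            IsoformClassification(
                read_id,
                CATEGORY_FUSION,
                partner_genes=[g for g in seg_genes if g is not None],
                evidence=[
                    "partner genes: " + ",".join(str(g) for g in seg_genes),
                    "interchromosomal" if inter else "intrachromosomal",
                ],
            )
        )
    return results
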