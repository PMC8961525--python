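"""Synthetic long-read transcriptome data with known ground truth.

The generator emulates the study design the pipeline targets: a multi-exon
reference annotation, full-length-read structures with 5'-end degradation,
injected novel isoforms (exactly one basic alternative-splicing operation
each), novel intergenic loci, inter/intra-chromosomal fusion reads,
binomially sampled inclusion/skipping junction counts under
condition-specific true exon-inclusion ratios, and negative-binomially
sampled gene counts with known fold-changes for two conditions with three
replicates each.

Every emitted record is labeled in :class:`GroundTruth`, which downstream
recovery and calibration tests compare against.

Only 5' truncation is simulated: library construction selects on the
poly(A) tail, anchoring the 3' end, so 5' degradation is the dominant
artifact class in full-length read sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .model import (
    Exon,
    GenomeAnnotation,
    JunctionTable,
    JUNCTION_COLUMNS,
    Transcript,
    fusion_breakpoint_key,
)

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe the emulated study at toy scale: 50 multi-exon genes
    on 2 chromosomes, one injected novel isoform per basic AS type per
    gene, 3 novel intergenic loci, 2 fusion reads (interchromosomal
    fraction from the study's observed 18/19), ~17% of reads 5'-degraded
    (the study observed 83% of reads intact at the first splice donor),
    3 + 3 replicates, junction depth 50, and negative-binomial gene counts
    (mean 100, dispersion 0.1) with |log2FC| = 2 on differential genes.
    """

    n_genes: int = 50
    exon_count_range: tuple[int, int] = (3, 8)
    exon_len_range: tuple[int, int] = (100, 300)
    intron_len_range: tuple[int, int] = (500, 2000)
    n_chroms: int = 2
    intergenic_gap: int = 8000
    novel_isoform_rate: float = 1.0
    novel_locus_count: int = 3
    novel_single_exon_fraction: float = 2 / 3
    fusion_count: int = 2
    fusion_interchrom_fraction: float = 18 / 19
    reads_per_transcript: int = 3
    five_prime_truncation_prob: float = 0.17
    n_replicates_per_condition: int = 3
    junction_depth: float = 50.0
    ei_null: float = 0.5
    ei_effects: list[tuple[str, float]] = field(default_factory=list)
    das_event_fraction: float = 0.3
    das_delta_ei: float = 0.3
    das_delta_threshold: float = 0.05
    expr_mean: float = 100.0
    expr_dispersion: float = 0.1
    de_log2fc_effects: list[tuple[str, float]] = field(default_factory=list)
    de_gene_fraction: float = 0.1
    de_log2fc: float = 2.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in (
            "novel_isoform_rate", "novel_single_exon_fraction",
            "fusion_interchrom_fraction", "five_prime_truncation_prob",
            "das_event_fraction", "de_gene_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.ei_null <= 1:
            raise ConfigurationError("ei_null must be in [0, 1]")
        if self.exon_len_range[0] <= 0 or self.intron_len_range[0] <= 0:
            raise ConfigurationError("exon/intron length ranges must be positive")
        if self.n_replicates_per_condition < 2:
            raise ConfigurationError("need >= 2 replicates per condition")
        if self.junction_depth <= 0:
            raise ConfigurationError("junction_depth must be > 0")
        if self.expr_mean < 0:
            raise ConfigurationError("expr_mean must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    @property
    def samples(self) -> dict[str, str]:
        """sample id -> condition label, A/B with n replicates each."""
        out = {}
        for cond in ("A", "B"):
            for r in range(1, self.n_replicates_per_condition + 1):
                out[f"{cond}{r}"] = cond
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("exon_count_range", "exon_len_range", "intron_len_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "ei_effects" in d:
            d["ei_effects"] = [tuple(x) for x in d["ei_effects"]]
        if "de_log2fc_effects" in d:
            d["de_log2fc_effects"] = [tuple(x) for x in d["de_log2fc_effects"]]
        return cls(**d)


@dataclass
class TrueEvent:
    event_id: str
    type: str
    gene_id: str
    chrom: str
    strand: str
    inclusion_junctions: frozenset[tuple[int, int]]
    exclusion_junctions: frozenset[tuple[int, int]]


@dataclass
class GroundTruth:
    """Labels for every emitted record; the oracle for recovery tests."""

    true_class: dict[str, str] = field(default_factory=dict)        # read id -> category
    true_isoform: dict[str, str] = field(default_factory=dict)      # read id -> structure id
    true_events: dict[str, TrueEvent] = field(default_factory=dict)
    true_ei: dict[tuple[str, str], float] = field(default_factory=dict)
    true_das: set[str] = field(default_factory=set)
    true_fusion: dict[str, tuple[str, str, bool]] = field(default_factory=dict)
    true_log2fc: dict[str, float] = field(default_factory=dict)
    true_deg: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# reference annotation


def simulate_reference(cfg: SimulationConfig) -> GenomeAnnotation:
    """A toy reference: non-overlapping multi-isoform genes on both strands.

    Genes are laid out left to right with ``intergenic_gap`` spacing,
    round-robin over chromosomes; each gene carries 1-3 isoforms sharing
    exons (secondary isoforms skip one internal exon of the primary).
    """
    rng = cfg.rng(1)
    genes: dict[str, list[Transcript]] = {}
    cursors = {f"chr{c + 1}": 10_000 for c in range(cfg.n_chroms)}
    for g in range(cfg.n_genes):
        chrom = f"chr{(g % cfg.n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"gene_{g + 1:03d}"
        n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        pos = cursors[chrom]
        exons: list[Exon] = []
        for k in range(n_exons):
            length = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
            exons.append(Exon(pos, pos + length))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
        txs = [Transcript(f"{gid}.t1", chrom, strand, list(exons), source="reference", gene_id=gid)]
        if n_exons >= 3:
            n_extra = int(rng.integers(0, 3))
            skippable = list(range(1, n_exons - 1))
            rng.shuffle(skippable)
            for e_i, skip in enumerate(skippable[:n_extra]):
                alt = [e for k, e in enumerate(exons) if k != skip]
                txs.append(
                    Transcript(f"{gid}.t{e_i + 2}", chrom, strand, alt,
                               source="reference", gene_id=gid)
                )
        genes[gid] = txs
        cursors[chrom] = pos + cfg.intergenic_gap
    chrom_lengths = {c: cur + 50_000 for c, cur in cursors.items()}
    if cfg.n_genes == 0:
        chrom_lengths = {f"chr{c + 1}": 100_000 for c in range(cfg.n_chroms)}
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# read structures and injected variation


def _inject_es(exons: list[Exon], j: int):
    new = [e for k, e in enumerate(exons) if k != j]
    inc = frozenset({(exons[j - 1].end, exons[j].start), (exons[j].end, exons[j + 1].start)})
    exc = frozenset({(exons[j - 1].end, exons[j + 1].start)})
    return new, inc, exc


def _inject_ir(exons: list[Exon], j: int):
    # retain the intron between exons j and j+1
    new = exons[:j] + [Exon(exons[j].start, exons[j + 1].end)] + exons[j + 2:]
    exc = frozenset({(exons[j].end, exons[j + 1].start)})
    return new, frozenset(), exc


def _inject_acceptor_shift(exons: list[Exon], j: int, delta: int, strand: str):
    """Move the acceptor of exon j (transcription sense) 'inward' by delta."""
    if strand == "+":
        shifted = Exon(exons[j].start + delta, exons[j].end)
        inc_j = (exons[j - 1].end, exons[j].start)
        exc_j = (exons[j - 1].end, shifted.start)
    else:
        shifted = Exon(exons[j].start, exons[j].end - delta)
        inc_j = (exons[j].end, exons[j + 1].start)
        exc_j = (shifted.end, exons[j + 1].start)
    new = exons[:j] + [shifted] + exons[j + 1:]
    return new, frozenset({inc_j}), frozenset({exc_j})


def _inject_donor_shift(exons: list[Exon], j: int, delta: int, strand: str):
    if strand == "+":
        shifted = Exon(exons[j].start, exons[j].end - delta)
        inc_j = (exons[j].end, exons[j + 1].start)
        exc_j = (shifted.end, exons[j + 1].start)
    else:
        shifted = Exon(exons[j].start + delta, exons[j].end)
        inc_j = (exons[j - 1].end, exons[j].start)
        exc_j = (exons[j - 1].end, shifted.start)
    new = exons[:j] + [shifted] + exons[j + 1:]
    return new, frozenset({inc_j}), frozenset({exc_j})


def _inject_mee(exons: list[Exon], j: int, rng: np.random.Generator):
    """Replace internal exon j with a non-overlapping exon in the 3' intron."""
    gap_lo, gap_hi = exons[j].end + 20, exons[j + 1].start - 20
    alt_len = min(150, (gap_hi - gap_lo) // 2)
    if alt_len < 30:
        return None
    start = int(rng.integers(gap_lo, gap_hi - alt_len))
    alt = Exon(start, start + alt_len)
    new = exons[:j] + [alt] + exons[j + 1:]
    a_inc = frozenset({(exons[j - 1].end, exons[j].start), (exons[j].end, exons[j + 1].start)})
    a_exc = frozenset({(exons[j - 1].end, alt.start), (alt.end, exons[j + 1].start)})
    # inclusion = side with more exonic bases between the anchors
    if len(alt) > len(exons[j]) or (len(alt) == len(exons[j]) and alt.start < exons[j].start):
        a_inc, a_exc = a_exc, a_inc
    return new, a_inc, a_exc


def _truncate_five_prime(exons: list[Exon], strand: str, rng: np.random.Generator) -> list[Exon]:
    """Degrade the 5' end: drop leading exon(s) or move the 5' terminus inward."""
    if strand == "+":
        if len(exons) > 1 and rng.random() < 0.5:
            k = int(rng.integers(1, len(exons)))
            return exons[k:]
        first = exons[0]
        shift = int(rng.integers(1, max(2, len(first) // 2)))
        return [Exon(first.start + shift, first.end)] + exons[1:]
    else:
        if len(exons) > 1 and rng.random() < 0.5:
            k = int(rng.integers(1, len(exons)))
            return exons[:-k]
        last = exons[-1]
        shift = int(rng.integers(1, max(2, len(last) // 2)))
        return exons[:-1] + [Exon(last.start, last.end - shift)]


def simulate_reads(
    cfg: SimulationConfig, ann: GenomeAnnotation
) -> tuple[list[Transcript], GroundTruth]:
    """Emit full-length-read structures and label them in GroundTruth.

    Faithful copies of every reference isoform (Poisson multiplicity,
    at least one), 5'-truncated with probability
    ``five_prime_truncation_prob``; one injected novel isoform per basic AS
    type per gene with probability ``novel_isoform_rate``; novel intergenic
    loci; and fusion reads joining the 5' exons of one gene to the 3' exons
    of another (emitted as two segments sharing a ``read_id``).
    """
    if not ann.genes and (cfg.novel_locus_count or cfg.fusion_count):
        raise ConfigurationError("cannot place novel loci/fusions without a reference")
    rng = cfg.rng(2)
    reads: list[Transcript] = []
    truth = GroundTruth()

    def emit_copies(structure_id, chrom, strand, exons, category, gene_id, n=None):
        k = n if n is not None else max(1, int(rng.poisson(cfg.reads_per_transcript)))
        for c in range(k):
            ex = list(exons)
            if (
                category == "known"
                and rng.random() < cfg.five_prime_truncation_prob
                and (len(ex) > 1 or len(ex[0]) > 4)
            ):
                ex = _truncate_five_prime(ex, strand, rng)
            rid = f"read_{structure_id}_{c + 1}"
            reads.append(
                Transcript(rid, chrom, strand, ex, source="flnc_read", gene_id=gene_id)
            )
            truth.true_class[rid] = category
            truth.true_isoform[rid] = structure_id

    # faithful copies of reference isoforms
    for gid in sorted(ann.genes):
        for t in ann.genes[gid]:
            emit_copies(t.id, t.chrom, t.strand, t.exons, "known", gid)

    # injected novel isoforms: exactly one AS operation each
    for gid in sorted(ann.genes):
        primary = ann.genes[gid][0]
        exons, strand = primary.exons, primary.strand
        known_chains = {t.splice_chain for t in ann.genes[gid]}
        if len(exons) < 3:
            continue
        internal = list(range(1, len(exons) - 1))
        for ev_type in ("ES", "IR", "AAS", "ADS", "MEE"):
            if rng.random() >= cfg.novel_isoform_rate:
                continue
            result = None
            for j in rng.permutation(internal):
                j = int(j)
                if ev_type == "ES":
                    result = _inject_es(exons, j)
                elif ev_type == "IR":
                    result = _inject_ir(exons, j)
                elif ev_type == "AAS":
                    delta = min(30, len(exons[j]) - 20)
                    result = _inject_acceptor_shift(exons, j, delta, strand) if delta > 0 else None
                elif ev_type == "ADS":
                    delta = min(30, len(exons[j]) - 20)
                    result = _inject_donor_shift(exons, j, delta, strand) if delta > 0 else None
                elif ev_type == "MEE":
                    result = _inject_mee(exons, j, rng)
                if result is None:
                    continue
                new_exons = result[0]
                chain = Transcript("tmp", primary.chrom, strand, list(new_exons)).splice_chain
                if chain in known_chains:
                    result = None
                    continue
                break
            if result is None:
                continue
            new_exons, inc_j, exc_j = result
            known_chains.add(
                Transcript("tmp", primary.chrom, strand, list(new_exons)).splice_chain
            )
            sid = f"{gid}.novel_{ev_type}"
            emit_copies(sid, primary.chrom, strand, new_exons, "novel_isoform", gid)
            ev_id = f"{gid}:{ev_type}"
            truth.true_events[ev_id] = TrueEvent(
                ev_id, ev_type, gid, primary.chrom, strand, inc_j, exc_j
            )

    # novel intergenic loci
    if cfg.novel_locus_count:
        gaps = _intergenic_gaps(ann)
        if len(gaps) < cfg.novel_locus_count:
            raise ConfigurationError(
                f"not enough intergenic space: {len(gaps)} gaps for "
                f"{cfg.novel_locus_count} novel loci"
            )
        rng.shuffle(gaps)
        n_single = round(cfg.novel_single_exon_fraction * cfg.novel_locus_count)
        for i in range(cfg.novel_locus_count):
            chrom, lo, hi = gaps[i]
            strand = "+" if rng.random() < 0.5 else "-"
            sid = f"novel_locus_{i + 1}"
            if i < n_single:
                length = int(rng.integers(*cfg.exon_len_range))
                exons = [Exon(lo, lo + length)]
            else:
                exons = []
                pos = lo
                for _ in range(int(rng.integers(2, 5))):
                    length = int(rng.integers(*cfg.exon_len_range))
                    exons.append(Exon(pos, pos + length))
                    pos += length + int(rng.integers(200, 800))
            emit_copies(sid, chrom, strand, exons, "novel_gene", None)

    # fusion reads: 5' exons of one gene joined to 3' exons of another
    gids = sorted(g for g in ann.genes if len(ann.genes[g][0].exons) >= 2)
    n_inter = round(cfg.fusion_interchrom_fraction * cfg.fusion_count)
    made = 0
    for i in range(cfg.fusion_count):
        want_inter = i < n_inter
        pair = _pick_fusion_pair(ann, gids, want_inter, rng)
        if pair is None:
            logger.warning("could not place %schromosomal fusion %d",
                           "inter" if want_inter else "intra", i + 1)
            continue
        ga, gb = pair
        ta, tb = ann.genes[ga][0], ann.genes[gb][0]
        ka = max(1, len(ta.exons) // 2)
        kb = max(1, len(tb.exons) // 2)
        seg_a_exons = ta.exons[:ka] if ta.strand == "+" else ta.exons[-ka:]
        seg_b_exons = tb.exons[-kb:] if tb.strand == "+" else tb.exons[:kb]
        rid = f"fusion_{made + 1}"
        seg1 = Transcript(f"{rid}_seg1", ta.chrom, ta.strand, list(seg_a_exons),
                          source="flnc_read", read_id=rid)
        seg2 = Transcript(f"{rid}_seg2", tb.chrom, tb.strand, list(seg_b_exons),
                          source="flnc_read", read_id=rid)
        reads.extend([seg1, seg2])
        truth.true_class[rid] = "fusion"
        truth.true_fusion[rid] = (ga, gb, ta.chrom != tb.chrom)
        made += 1

    _assign_splicing_effects(cfg, truth)
    return reads, truth


def _intergenic_gaps(ann: GenomeAnnotation, margin: int = 2000, min_width: int = 3000):
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in ann.chrom_lengths}
    for gid in ann.genes:
        chrom, _, s, e = ann.gene_span(gid)
        spans[chrom].append((s, e))
    gaps = []
    for chrom, length in sorted(ann.chrom_lengths.items()):
        occupied = sorted(spans.get(chrom, []))
        prev = 0
        for s, e in occupied + [(length, length)]:
            if s - prev >= min_width + 2 * margin:
                gaps.append((chrom, prev + margin, s - margin))
            prev = max(prev, e)
    return gaps


def _pick_fusion_pair(ann, gids, want_inter, rng):
    if len(gids) < 2:
        return None
    for _ in range(200):
        ga, gb = (str(g) for g in rng.choice(gids, size=2, replace=False))
        ca = ann.genes[ga][0].chrom
        cb = ann.genes[gb][0].chrom
        if want_inter and ca != cb:
            return ga, gb
        if not want_inter and ca == cb:
            # order so the breakpoint runs left to right on the chromosome
            if ann.genes[ga][0].start > ann.genes[gb][0].start:
                ga, gb = gb, ga
            return ga, gb
    return None


def _assign_splicing_effects(cfg: SimulationConfig, truth: GroundTruth) -> None:
    """Fix true per-condition EI for every injected event.

    Explicit ``ei_effects`` (event id, dEI) take precedence; otherwise a
    seeded fraction ``das_event_fraction`` of events receives alternating
    +/- ``das_delta_ei``.  ``true_das`` holds events with |dEI| above the
    decision threshold.
    """
    rng = cfg.rng(3)
    effects = dict(cfg.ei_effects)
    if not effects:
        ev_ids = sorted(truth.true_events)
        n_das = round(cfg.das_event_fraction * len(ev_ids))
        chosen = sorted(str(e) for e in rng.choice(ev_ids, size=n_das, replace=False)) if n_das else []
        for k, ev in enumerate(chosen):
            effects[ev] = cfg.das_delta_ei if k % 2 == 0 else -cfg.das_delta_ei
    for ev_id in truth.true_events:
        delta = effects.get(ev_id, 0.0)
        ei_a = cfg.ei_null
        ei_b = float(np.clip(cfg.ei_null + delta, 0.0, 1.0))
        truth.true_ei[(ev_id, "A")] = ei_a
        truth.true_ei[(ev_id, "B")] = ei_b
        if abs(ei_b - ei_a) > cfg.das_delta_threshold:
            truth.true_das.add(ev_id)


# ---------------------------------------------------------------------------
# junction and gene counts


def simulate_junction_counts(
    cfg: SimulationConfig,
    truth: GroundTruth,
    reads: list[Transcript] | None = None,
) -> tuple[JunctionTable, JunctionTable]:
    """Per-sample junction counts; returns (junctions, retention_evidence).

    For each injected event and sample, depth ~ Poisson(junction_depth),
    inclusion ~ Binomial(depth, EI of the sample's condition), skipping =
    depth - inclusion; inclusion counts are written to every diagnostic
    inclusion junction (one molecule supports them all) and skipping counts
    to the exclusion junctions.  IR inclusion (retention) evidence goes to
    the separate retention table keyed by the retained intron.  All other
    introns of the emitted reads, and fusion breakpoints, receive Poisson
    background coverage so junction-based rescue and fusion support are
    exercised.
    """
    rng = cfg.rng(4)
    samples = cfg.samples
    rows: dict[tuple, int] = {}
    retention_rows: dict[tuple, int] = {}

    for ev_id in sorted(truth.true_events):
        ev = truth.true_events[ev_id]
        for sample, cond in samples.items():
            depth = int(rng.poisson(cfg.junction_depth))
            ei = truth.true_ei[(ev_id, cond)]
            n_inc = int(rng.binomial(depth, ei)) if depth > 0 else 0
            n_skip = depth - n_inc
            if ev.type == "IR":
                for d, a in sorted(ev.exclusion_junctions):
                    retention_rows[(ev.chrom, d, a, ev.strand, sample)] = n_inc
                    rows[(ev.chrom, d, a, ev.strand, sample)] = n_skip
            else:
                for d, a in sorted(ev.inclusion_junctions):
                    rows[(ev.chrom, d, a, ev.strand, sample)] = n_inc
                for d, a in sorted(ev.exclusion_junctions):
                    rows[(ev.chrom, d, a, ev.strand, sample)] = n_skip

    if reads is not None:
        by_read: dict[str, list[Transcript]] = {}
        for t in reads:
            by_read.setdefault(t.read_id or t.id, []).append(t)
        for t in sorted(reads, key=lambda t: t.id):
            for d, a in t.introns:
                for sample in samples:
                    key = (t.chrom, d, a, t.strand, sample)
                    if key not in rows:
                        rows[key] = max(1, int(rng.poisson(cfg.junction_depth)))
        # fusion breakpoint support
        for rid in sorted(truth.true_fusion):
            segs = sorted(by_read.get(rid, []), key=lambda t: t.id)
            for a, b in zip(segs, segs[1:]):
                pos5 = a.end if a.strand == "+" else a.start
                pos3 = b.start if b.strand == "+" else b.end
                key = fusion_breakpoint_key(a.chrom, pos5, b.chrom, pos3, a.strand)
                for sample in samples:
                    rows[(*key, sample)] = max(1, int(rng.poisson(cfg.junction_depth)))

    def to_table(d: dict[tuple, int]) -> JunctionTable:
        recs = [(c, don, acc, s, smp, n) for (c, don, acc, s, smp), n in sorted(d.items())]
        return JunctionTable(pd.DataFrame(recs, columns=JUNCTION_COLUMNS))

    return to_table(rows), to_table(retention_rows)


def simulate_gene_counts(
    cfg: SimulationConfig,
    ann: GenomeAnnotation,
    truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Negative-binomial gene counts (gene x sample) with known log2FCs.

    Condition means are ``expr_mean * 2^(+-log2FC/2)``; variance follows
    mean + dispersion * mean^2.  Explicit ``de_log2fc_effects`` take
    precedence; otherwise a seeded fraction of genes gets alternating
    +/- ``de_log2fc``.  True labels are recorded on ``truth`` when given.
    """
    rng = cfg.rng(5)
    gids = sorted(ann.genes)
    effects = dict(cfg.de_log2fc_effects)
    for g in effects:
        if g not in ann.genes:
            raise ConfigurationError(f"de_log2fc_effects references unknown gene {g}")
    if not effects and gids:
        n_de = round(cfg.de_gene_fraction * len(gids))
        chosen = sorted(str(g) for g in rng.choice(gids, size=n_de, replace=False)) if n_de else []
        for k, g in enumerate(chosen):
            effects[g] = cfg.de_log2fc if k % 2 == 0 else -cfg.de_log2fc

    samples = cfg.samples
    data = np.zeros((len(gids), len(samples)), dtype=int)
    alpha = cfg.expr_dispersion
    for i, gid in enumerate(gids):
        lfc = effects.get(gid, 0.0)
        mu = {"A": cfg.expr_mean * 2 ** (-lfc / 2), "B": cfg.expr_mean * 2 ** (lfc / 2)}
        for j, (sample, cond) in enumerate(samples.items()):
            m = mu[cond]
            if alpha <= 1e-12:
                data[i, j] = rng.poisson(m)
            else:
                n_param = 1.0 / alpha
                p_param = n_param / (n_param + m)
                data[i, j] = rng.negative_binomial(n_param, p_param)
        if truth is not None:
            truth.true_log2fc[gid] = lfc
            if abs(lfc) > 1.0:
                truth.true_deg.add(gid)
    return pd.DataFrame(data, index=gids, columns=list(samples))


def simulate_event_counts(
    n_events: int,
    delta_ei: float = 0.0,
    ei_null: float = 0.5,
    junction_depth: float = 50.0,
    n_replicates: int = 3,
    seed: int = 0,
    l_inc: int = 2,
    l_exc: int = 1,
):
    """Stand-alone per-event junction counts for test calibration studies.

    Each event gets, per sample, depth ~ Poisson(junction_depth) molecules;
    inclusion molecules ~ Binomial(depth, EI of the condition) with
    EI_A = ei_null and EI_B = ei_null + delta_ei; every inclusion molecule
    contributes a count to each of the ``l_inc`` inclusion junctions (and
    likewise for skipping), matching how the dataset-level generator fills
    the junction table.  Returns a list of
    :class:`~isoscan.das.EventCounts`.
    """
    from .das import EventCounts  # avoid import cycle

    rng = np.random.default_rng(seed)
    ei_a = ei_null
    ei_b = float(np.clip(ei_null + delta_ei, 0.0, 1.0))
    condition = {}
    for cond in ("A", "B"):
        for r in range(1, n_replicates + 1):
            condition[f"{cond}{r}"] = cond
    out = []
    for k in range(n_events):
        inclusion, skipping = {}, {}
        for sample, cond in condition.items():
            depth = int(rng.poisson(junction_depth))
            ei = ei_a if cond == "A" else ei_b
            n_inc = int(rng.binomial(depth, ei)) if depth > 0 else 0
            inclusion[sample] = n_inc * l_inc
            skipping[sample] = (depth - n_inc) * l_exc
        out.append(
            EventCounts(f"sim_ev_{k}", "ES", inclusion, skipping, dict(condition),
                        l_inc, l_exc)
        )
    return out


def random_locus(
    rng: np.random.Generator,
    max_isoforms: int = 5,
    max_exons: int = 8,
    locus_id: str = "locus_r",
) -> "Locus":
    """A random locus of structurally perturbed isoforms (stress-test input).

    Starts from a random base exon chain and derives isoforms by randomly
    dropping exons, merging adjacent exons (intron retention), shifting
    internal boundaries, and substituting intra-intron exons — producing
    the full range of basic and complex bubbles for classifier validation.
    """
    from .annotate import Locus  # local import to avoid a cycle

    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(rng.integers(2, max_exons + 1))
    pos = 1000
    base: list[Exon] = []
    for k in range(n_exons):
        length = int(rng.integers(80, 250))
        base.append(Exon(pos, pos + length))
        pos += length + int(rng.integers(150, 900))
    members: list[Transcript] = [
        Transcript(f"{locus_id}.i1", "chrR", strand, list(base), source="collapsed_isoform")
    ]
    n_iso = int(rng.integers(2, max_isoforms + 1))
    for i in range(2, n_iso + 1):
        exons = [Exon(e.start, e.end) for e in base]
        for _ in range(int(rng.integers(1, 4))):
            op = rng.integers(0, 4)
            if op == 0 and len(exons) > 2:  # drop an internal exon
                j = int(rng.integers(1, len(exons) - 1))
                exons.pop(j)
            elif op == 1 and len(exons) > 1:  # retain an intron
                j = int(rng.integers(0, len(exons) - 1))
                exons[j : j + 2] = [Exon(exons[j].start, exons[j + 1].end)]
            elif op == 2:  # shift an exon boundary
                j = int(rng.integers(0, len(exons)))
                e = exons[j]
                if len(e) > 60:
                    if rng.random() < 0.5:
                        exons[j] = Exon(e.start + int(rng.integers(10, 40)), e.end)
                    else:
                        exons[j] = Exon(e.start, e.end - int(rng.integers(10, 40)))
            elif op == 3 and len(exons) > 2:  # swap in an intra-intron exon
                j = int(rng.integers(1, len(exons) - 1))
                lo, hi = exons[j - 1].end + 10, exons[j + 1].start - 10
                if hi - lo > 60:
                    s = int(rng.integers(lo, hi - 50))
                    exons[j] = Exon(s, s + int(rng.integers(40, min(200, hi - s))))
        try:
            members.append(
                Transcript(f"{locus_id}.i{i}", "chrR", strand, exons, source="collapsed_isoform")
            )
        except Exception:
            continue
    return Locus(
        id=locus_id,
        chrom="chrR",
        strand=strand,
        span=(min(t.start for t in members), max(t.end for t in members)),
        members=members,
    )


# ---------------------------------------------------------------------------
# one-call bundle


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: GenomeAnnotation
    reads: list[Transcript]
    truth: GroundTruth
    junctions: JunctionTable
    retention: JunctionTable
    gene_counts: pd.DataFrame
    condition_map: dict[str, str]


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate the full synthetic dataset (deterministic given cfg.seed)."""
    ann = simulate_reference(cfg)
    reads, truth = simulate_reads(cfg, ann)
    junctions, retention = simulate_junction_counts(cfg, truth, reads)
    counts = simulate_gene_counts(cfg, ann, truth)
    return SimulatedDataset(cfg, ann, reads, truth, junctions, retention, counts, cfg.samples)
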