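"""Core genomic data model.

All coordinates are 0-based half-open ``[start, end)`` internally; file
readers/writers convert at the boundary (GTF/GFF3 are 1-based inclusive,
BED12 is already half-open).

A :class:`Transcript` is the universal structural unit: reference isoforms,
aligned full-length reads, and collapsed isoforms are all strand-aware exon
chains on one chromosome.  Reads that align in several pieces (e.g. fusion
candidates spanning two loci or two chromosomes) are represented as multiple
``Transcript`` segments sharing a ``read_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: separator used to key an inter-chromosomal fusion breakpoint in the
#: junction table: chrom column holds "chromA~chromB"
FUSION_CHROM_SEP = "~"


class ValidationError(ValueError):
    """Raised when a structure violates a model invariant."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic interval, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(f"exon requires start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Transcript:
    """A strand-aware exon chain on one chromosome.

    Parameters
    ----------
    id : str
        Unique identifier of the structure.
    chrom, strand : str
        Chromosome name and ``+``/``-`` strand.
    exons : list of Exon
        Sorted by start, non-overlapping, separated by introns of >= 1 bp.
    source : str
        One of ``reference``, ``flnc_read``, ``collapsed_isoform``.
    support_count : int
        Number of full-length reads collapsed into this structure.
    gene_id : str, optional
        Gene the structure belongs to (reference annotation) or was
        assigned to.
    read_id : str, optional
        Identifier of the underlying read; segments of one split-aligned
        read share it.  Defaults to ``id``.
    """

    id: str
    chrom: str
    strand: str
    exons: list[Exon]
    source: str = "flnc_read"
    support_count: int = 1
    gene_id: str | None = None
    read_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.id}: transcript needs at least one exon")
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{self.id}: exons must be separated by >= 1 bp introns "
                    f"([{a.start},{a.end}) then [{b.start},{b.end}))"
                )
        if self.support_count < 1:
            raise ValidationError(f"{self.id}: support_count must be >= 1")
        if self.read_id is None:
            self.read_id = self.id

    # -- derived structure -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> tuple[int, int]:
        """Genomic span (first exon start, last exon end)."""
        return (self.start, self.end)

    @property
    def spliced_length(self) -> int:
        """Sum of exon lengths (never the genomic span when introns exist)."""
        return sum(len(e) for e in self.exons)

    @property
    def splice_chain(self) -> tuple[int, ...]:
        """Ordered internal splice sites, transcript termini excluded.

        ``(e1.end, e2.start, e2.end, ..., en.start)`` in genomic order;
        empty for single-exon transcripts.
        """
        sites: list[int] = []
        for e in self.exons[:-1]:
            sites.append(e.end)
        inner = [e.start for e in self.exons[1:]]
        chain: list[int] = []
        for end, start in zip(sites, inner):
            chain.extend((end, start))
        return tuple(chain)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intron intervals ``(donor, acceptor)`` in genome coordinates."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def splice_sites(self) -> frozenset[int]:
        return frozenset(self.splice_chain)

    @property
    def is_single_exon(self) -> bool:
        return len(self.exons) == 1

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the 5' terminus (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def with_(self, **kw) -> "Transcript":
        return replace(self, **kw)


@dataclass
class GenomeAnnotation:
    """Reference (or derived) annotation: transcripts grouped by gene."""

    genes: dict[str, list[Transcript]] = field(default_factory=dict)
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gid, txs in self.genes.items():
            chroms = {t.chrom for t in txs}
            strands = {t.strand for t in txs}
            if len(chroms) > 1 or len(strands) > 1:
                raise ValidationError(f"gene {gid}: transcripts must share chrom and strand")
            for t in txs:
                if self.chrom_lengths and t.chrom not in self.chrom_lengths:
                    raise ValidationError(f"{t.id}: chrom {t.chrom} not in chrom_lengths")

    @property
    def transcripts(self) -> list[Transcript]:
        return [t for txs in self.genes.values() for t in txs]

    @property
    def n_transcripts(self) -> int:
        return sum(len(v) for v in self.genes.values())

    def gene_span(self, gene_id: str) -> tuple[str, str, int, int]:
        txs = self.genes[gene_id]
        return (
            txs[0].chrom,
            txs[0].strand,
            min(t.start for t in txs),
            max(t.end for t in txs),
        )

    def splice_sites_of(self, gene_id: str) -> frozenset[int]:
        """Union of internal splice sites over a gene's transcripts."""
        sites: set[int] = set()
        for t in self.genes[gene_id]:
            sites.update(t.splice_chain)
        return frozenset(sites)

    def introns_of(self, gene_id: str | None = None) -> frozenset[tuple[str, int, int, str]]:
        """Annotated introns as ``(chrom, donor, acceptor, strand)`` keys."""
        txs = self.genes[gene_id] if gene_id else self.transcripts
        out: set[tuple[str, int, int, str]] = set()
        for t in txs:
            for d, a in t.introns:
                out.add((t.chrom, d, a, t.strand))
        return frozenset(out)


JUNCTION_COLUMNS = ["chrom", "donor", "acceptor", "strand", "sample", "count"]


@dataclass
class JunctionTable:
    """Per-sample splice-junction support counts.

    Keyed by intron coordinates: donor = intron start, acceptor = intron end
    (genome coordinates, strand-aware).  Fusion breakpoints between two
    chromosomes use ``chrom = "chromA~chromB"`` with donor/acceptor the
    segment boundary coordinates.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in JUNCTION_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"junction table missing columns: {missing}")
        self.df = self.df[JUNCTION_COLUMNS].copy()
        key = ["chrom", "donor", "acceptor", "strand", "sample"]
        if self.df.duplicated(subset=key).any():
            raise ValidationError("junction table has duplicate (junction, sample) keys")
        if (self.df["count"] < 0).any():
            raise ValidationError("junction counts must be >= 0")

    @classmethod
    def empty(cls) -> "JunctionTable":
        return cls(pd.DataFrame(columns=JUNCTION_COLUMNS))

    @classmethod
    def from_records(cls, records) -> "JunctionTable":
        return cls(pd.DataFrame(records, columns=JUNCTION_COLUMNS))

    @classmethod
    def read_tsv(cls, path) -> "JunctionTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "sample": str})
        return cls(df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def samples(self) -> list[str]:
        return sorted(self.df["sample"].unique())

    def _index(self) -> dict[tuple, dict[str, int]]:
        """Lazy lookup: (chrom, donor, acceptor, strand) -> sample counts."""
        idx = getattr(self, "_idx", None)
        if idx is None:
            idx = {}
            for c, d, a, s, smp, n in self.df.itertuples(index=False, name=None):
                idx.setdefault((c, d, a, s), {})[smp] = int(n)
            self._idx = idx
        return idx

    def supported(self, chrom: str, donor: int, acceptor: int, strand: str) -> bool:
        """True if any sample has count > 0 for this junction."""
        counts = self._index().get((chrom, donor, acceptor, strand))
        return counts is not None and any(n > 0 for n in counts.values())

    def sample_counts(self, chrom: str, junctions, strand: str) -> dict[str, int]:
        """Summed counts per sample over a set of ``(donor, acceptor)`` introns."""
        totals: dict[str, int] = {s: 0 for s in self.samples}
        idx = self._index()
        for d, a in junctions:
            for smp, n in idx.get((chrom, d, a, strand), {}).items():
                totals[smp] += n
        return totals


def fusion_breakpoint_key(
    chrom5: str, pos5: int, chrom3: str, pos3: int, strand: str
) -> tuple[str, int, int, str]:
    """Junction-table key for a fusion breakpoint.

    Intra-chromosomal breakpoints look like ordinary junctions; breakpoints
    joining two chromosomes encode both names in the chrom field.
    """
    if chrom5 == chrom3:
        donor, acceptor = sorted((pos5, pos3))
        return (chrom5, donor, acceptor, strand)
    return (f"{chrom5}{FUSION_CHROM_SEP}{chrom3}", pos5, pos3, strand)
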