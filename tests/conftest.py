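import pytest
from hypothesis import settings

from isoscan.model import Exon, GenomeAnnotation, JunctionTable, Transcript

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def tx(tid, exons, strand="+", chrom="chr1", **kw):
    """Shorthand transcript builder for fixtures."""
    return Transcript(tid, chrom, strand, [Exon(s, e) for s, e in exons], **kw)


@pytest.fixture
def two_exon_gene():
    """One gene, one transcript with exons [0,100) and [200,300)."""
    t = tx("g1.t1", [(0, 100), (200, 300)], source="reference", gene_id="g1")
    return GenomeAnnotation(genes={"g1": [t]}, chrom_lengths={"chr1": 10_000})


@pytest.fixture
def empty_junctions():
    return JunctionTable.empty()
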