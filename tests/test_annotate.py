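"""Loci clustering, isoform collapse and classification rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from isoscan.annotate import (
    CATEGORY_FUSION,
    CATEGORY_KNOWN,
    CATEGORY_NOVEL_GENE,
    CATEGORY_NOVEL_ISOFORM,
    Locus,
    classify_isoform,
    cluster_loci,
    collapse_isoforms,
    detect_fusions,
    overlap_fraction,
    same_locus,
)
from isoscan.model import (
    Exon,
    GenomeAnnotation,
    JunctionTable,
    Transcript,
    ValidationError,
)

from conftest import tx


def make_locus(members, locus_id="L1"):
    return Locus(
        id=locus_id,
        chrom=members[0].chrom,
        strand=members[0].strand,
        span=(min(t.start for t in members), max(t.end for t in members)),
        members=members,
    )


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((0, 100), (80, 200), 0.20),
            ((0, 100), (0, 100), 1.0),
            ((0, 100), (100, 200), 0.0),  # abutting half-open intervals
            ((0, 1000), (400, 500), 1.0),  # containment vs shorter span
        ],
    )
    def test_fraction_of_shorter_span(self, a, b, expected):
        assert overlap_fraction(a, b) == pytest.approx(expected)

    def test_zero_length_span_rejected(self):
        with pytest.raises(ValidationError):
            overlap_fraction((5, 5), (0, 10))


class TestSameLocus:
    def test_identical_transcripts(self):
        a = tx("a", [(0, 100), (200, 300)])
        assert same_locus(a, a)

    def test_opposite_strand_never_same_locus(self):
        a = tx("a", [(0, 100), (200, 300)], strand="+")
        b = tx("b", [(0, 100), (200, 300)], strand="-")
        assert not same_locus(a, b)

    def test_span_overlap_without_exon_overlap(self):
        # spans overlap > 20% but exons interleave into introns
        a = tx("a", [(0, 100), (300, 400)])
        b = tx("b", [(120, 180), (220, 280)])
        assert overlap_fraction(a.span, b.span) >= 0.20
        # exhaustive exon-pair check confirms no overlapping exon pair
        assert all(
            min(ea.end, eb.end) <= max(ea.start, eb.start)
            for ea in a.exons for eb in b.exons
        )
        assert not same_locus(a, b)


def brute_force_components(reads, min_overlap=0.20):
    """Independent connected-components oracle (BFS on the full pair matrix)."""
    n = len(reads)
    seen, comps = set(), []
    adj = {
        i: [j for j in range(n) if j != i and same_locus(reads[i], reads[j], min_overlap)]
        for i in range(n)
    }
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in comp:
                continue
            comp.add(k)
            stack.extend(adj[k])
        seen |= comp
        comps.append(frozenset(reads[k].id for k in comp))
    return set(comps)


class TestClusterLoci:
    def test_transitive_chain_is_one_locus(self):
        # A~B and B~C but A and C do not overlap at all
        a = tx("A", [(0, 100)])
        b = tx("B", [(80, 220)])
        c = tx("C", [(200, 300)])
        assert same_locus(a, b) and same_locus(b, c) and not same_locus(a, c)
        loci = cluster_loci([a, b, c])
        assert len(loci) == 1 and len(loci[0].members) == 3

    def test_disjoint_genes_two_loci(self):
        loci = cluster_loci([tx("a", [(0, 100)]), tx("b", [(5000, 5100)])])
        assert len(loci) == 2

    def test_empty_input(self):
        assert cluster_loci([]) == []

    @settings(max_examples=40, deadline=None)
    @given(data=st.data())
    def test_matches_brute_force_components(self, data):
        n = data.draw(st.integers(1, 30))
        reads = []
        for i in range(n):
            start = data.draw(st.integers(0, 2000))
            strand = data.draw(st.sampled_from("+-"))
            n_ex = data.draw(st.integers(1, 3))
            exons, pos = [], start
            for _ in range(n_ex):
                ln = data.draw(st.integers(20, 300))
                exons.append(Exon(pos, pos + ln))
                pos += ln + data.draw(st.integers(1, 400))
            reads.append(Transcript(f"r{i}", "chr1", strand, exons))
        expected = brute_force_components(reads)
        got = {frozenset(t.id for t in L.members) for L in cluster_loci(reads)}
        assert got == expected


class TestCollapseRules:
    def ref(self):
        return GenomeAnnotation(genes={}, chrom_lengths={})

    def test_identical_chains_merge_keeping_longer_five_prime(self, empty_junctions):
        a = tx("a", [(0, 100), (200, 300)], support_count=2)
        b = tx("b", [(50, 100), (200, 300)], support_count=3)
        out = collapse_isoforms(make_locus([a, b]), empty_junctions, self.ref())
        assert len(out) == 1
        assert out[0].support_count == 5
        assert out[0].start == 0  # longer 5' end kept on + strand

    def test_five_prime_suffix_fragment_merges_into_parent(self, empty_junctions):
        big = tx("big", [(0, 100), (200, 300), (400, 500)], support_count=2)
        frag = tx("frag", [(250, 300), (400, 500)], support_count=2)
        out = collapse_isoforms(make_locus([big, frag]), empty_junctions, self.ref())
        assert [t.id for t in out] == ["big"]
        assert out[0].support_count == 4

    def test_five_prime_suffix_minus_strand(self, empty_junctions):
        big = tx("big", [(0, 100), (200, 300), (400, 500)], strand="-", support_count=2)
        frag = tx("frag", [(0, 100), (200, 260)], strand="-", support_count=2)
        out = collapse_isoforms(make_locus([big, frag]), empty_junctions, self.ref())
        assert [t.id for t in out] == ["big"]

    def test_unsupported_singleton_removed(self, empty_junctions):
        keep = tx("keep", [(0, 100), (200, 300)], support_count=2)
        lone = tx("lone", [(0, 100), (150, 300)], support_count=1)
        out = collapse_isoforms(make_locus([keep, lone]), empty_junctions, self.ref())
        assert [t.id for t in out] == ["keep"]

    def test_singleton_with_all_annotated_introns_retained(self, empty_junctions):
        ref_t = tx("ref", [(0, 100), (150, 300)], source="reference", gene_id="g")
        reference = GenomeAnnotation(genes={"g": [ref_t]})
        keep = tx("keep", [(0, 100), (200, 300)], support_count=2)
        lone = tx("lone", [(0, 100), (150, 300)], support_count=1)
        out = collapse_isoforms(make_locus([keep, lone]), empty_junctions, reference)
        assert {t.id for t in out} == {"keep", "lone"}

    def test_singleton_with_junction_support_retained(self):
        jt = JunctionTable.from_records([("chr1", 100, 150, "+", "A1", 4)])
        keep = tx("keep", [(0, 100), (200, 300)], support_count=2)
        lone = tx("lone", [(0, 100), (150, 300)], support_count=1)
        out = collapse_isoforms(make_locus([keep, lone]), jt, self.ref())
        assert {t.id for t in out} == {"keep", "lone"}

    def test_single_exon_singleton_vacuously_retained(self, empty_junctions):
        lone = tx("lone", [(0, 500)], support_count=1)
        out = collapse_isoforms(make_locus([lone]), empty_junctions, self.ref())
        assert [t.id for t in out] == ["lone"]

    def test_idempotent(self, empty_junctions):
        rng = np.random.default_rng(0)
        from isoscan.simulate import random_locus

        for k in range(20):
            locus = random_locus(rng, locus_id=f"L{k}")
            # multi-read support so the singleton filter cannot empty the locus
            locus.members = [m.with_(support_count=2) for m in locus.members]
            once = collapse_isoforms(locus, empty_junctions, self.ref())
            twice = collapse_isoforms(make_locus(once, "L"), empty_junctions, self.ref())
            assert {(t.splice_chain, t.support_count) for t in once} == {
                (t.splice_chain, t.support_count) for t in twice
            }

    def test_support_conserved_through_merges(self, empty_junctions):
        a = tx("a", [(0, 100), (200, 300)], support_count=3)
        b = tx("b", [(40, 100), (200, 300)], support_count=2)
        c = tx("c", [(250, 300)], support_count=4)  # 5' remnant over last exon
        out = collapse_isoforms(make_locus([a, b, c]), empty_junctions, self.ref())
        assert sum(t.support_count for t in out) == 9


class TestClassifyIsoform:
    @pytest.fixture
    def reference(self):
        t1 = tx("g1.t1", [(0, 100), (200, 300), (400, 500)], source="reference", gene_id="g1")
        single = tx("g2.t1", [(10_000, 11_000)], source="reference", gene_id="g2")
        return GenomeAnnotation(genes={"g1": [t1], "g2": [single]})

    def classify(self, iso, reference):
        return classify_isoform(iso, make_locus([iso]), reference)

    def test_identical_chain_is_known(self, reference):
        iso = tx("i", [(0, 100), (200, 300), (400, 500)])
        c = self.classify(iso, reference)
        assert c.category == CATEGORY_KNOWN
        assert c.matched_reference_transcript == "g1.t1"

    def test_terminal_differences_still_known(self, reference):
        iso = tx("i", [(20, 100), (200, 300), (400, 480)])
        assert self.classify(iso, reference).category == CATEGORY_KNOWN

    def test_shifted_acceptor_is_novel_isoform(self, reference):
        iso = tx("i", [(0, 100), (230, 300), (400, 500)])
        c = self.classify(iso, reference)
        assert c.category == CATEGORY_NOVEL_ISOFORM
        assert any("splice site" in e for e in c.evidence)

    def test_opposite_strand_overlap_is_novel_gene(self, reference):
        iso = tx("i", [(0, 100), (200, 300), (400, 500)], strand="-")
        c = self.classify(iso, reference)
        assert c.category == CATEGORY_NOVEL_GENE
        assert any("opposite strand" in e for e in c.evidence)

    def test_intergenic_is_novel_gene(self, reference):
        iso = tx("i", [(50_000, 50_500)])
        assert self.classify(iso, reference).category == CATEGORY_NOVEL_GENE

    def test_single_exon_over_multi_exon_gene_is_novel_isoform(self, reference):
        iso = tx("i", [(0, 450)])
        c = self.classify(iso, reference)
        assert c.category == CATEGORY_NOVEL_ISOFORM

    def test_single_exon_contained_in_single_exon_reference_is_known(self, reference):
        iso = tx("i", [(10_100, 10_900)])
        assert self.classify(iso, reference).category == CATEGORY_KNOWN


class TestDetectFusions:
    @pytest.fixture
    def reference(self):
        ga = tx("ga.t1", [(0, 100), (200, 300)], source="reference", gene_id="ga")
        gb = tx(
            "gb.t1", [(0, 100), (200, 300)], chrom="chr2", source="reference", gene_id="gb"
        )
        return GenomeAnnotation(genes={"ga": [ga], "gb": [gb]})

    def segments(self):
        s1 = tx("f1_seg1", [(0, 100)], read_id="f1")
        s2 = tx("f1_seg2", [(200, 300)], chrom="chr2", read_id="f1")
        return [s1, s2]

    def test_supported_breakpoint_is_fusion(self, reference):
        jt = JunctionTable.from_records([("chr1~chr2", 100, 200, "+", "A1", 5)])
        (f,) = detect_fusions(self.segments(), reference, jt)
        assert f.category == CATEGORY_FUSION
        assert f.partner_genes == ["ga", "gb"]
        assert "interchromosomal" in f.evidence

    def test_unsupported_breakpoint_is_not_fusion(self, reference, empty_junctions):
        assert detect_fusions(self.segments(), reference, empty_junctions) == []

    def test_insufficient_overlap_is_not_fusion(self, reference):
        jt = JunctionTable.from_records([("chr1~chr2", 400, 200, "+", "A1", 5)])
        # segment hangs off the gene: 10 bp shared of a 110 bp segment (~9%)
        s1 = tx("f1_seg1", [(290, 400)], read_id="f1")
        s2 = tx("f1_seg2", [(200, 300)], chrom="chr2", read_id="f1")
        assert overlap_fraction((290, 400), (0, 300)) < 0.20
        assert detect_fusions([s1, s2], reference, jt) == []

    def test_empty_segment_list_rejected(self, reference, empty_junctions):
        with pytest.raises(ValidationError):
            detect_fusions([], reference, empty_junctions)
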