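"""AS-event bubbles: detection, five-type classification, enumeration."""

import numpy as np
import pytest

from isoscan.events import (
    TYPE_AAS,
    TYPE_ADS,
    TYPE_COMPLEX,
    TYPE_ES,
    TYPE_IR,
    TYPE_MEE,
    classify_bubble,
    enumerate_events,
    event_junctions,
    event_multiplicities,
    find_bubbles,
)
from isoscan.model import ValidationError
from isoscan.naive import naive_enumerate_events
from isoscan.simulate import random_locus

from conftest import tx
from test_annotate import make_locus


OUTER = [((-500, -400), (600, 700))]  # shared flanking exons for context


def with_context(core_exons):
    (left, right) = OUTER[0]
    return [left] + core_exons + [right]


class TestFindBubbles:
    def test_identical_chains_no_bubbles(self):
        a = tx("a", [(0, 100), (200, 300)])
        b = tx("b", [(0, 100), (200, 300)])
        assert find_bubbles(a, b) == []

    def test_single_exon_pair_no_bubbles(self):
        assert find_bubbles(tx("a", [(0, 100)]), tx("b", [(0, 100)])) == []

    def test_exon_skip_bubble_anchored_at_shared_sites(self):
        a = tx("a", [(0, 100), (200, 300), (400, 500)])
        b = tx("b", [(0, 100), (400, 500)])
        (bub,) = find_bubbles(a, b)
        assert (bub.left, bub.right) == (100, 400)
        assert bub.sites_a == (200, 300) and bub.sites_b == ()

    def test_two_independent_differences_two_bubbles(self):
        a = tx("a", [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)])
        b = tx("b", [(0, 100), (400, 500), (600, 700), (830, 900)])
        bubbles = find_bubbles(a, b)
        assert len(bubbles) == 2


class TestClassifyBubble:
    def classify_pair(self, exons_a, exons_b, strand="+"):
        a = tx("a", with_context(exons_a), strand=strand)
        b = tx("b", with_context(exons_b), strand=strand)
        bubbles = find_bubbles(a, b)
        assert len(bubbles) == 1
        return classify_bubble(bubbles[0])

    def test_exon_skipping(self):
        assert self.classify_pair([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)]) == TYPE_ES

    def test_multi_exon_skip_is_still_es(self):
        t = self.classify_pair(
            [(0, 100), (200, 300), (350, 380), (400, 500)], [(0, 100), (400, 500)]
        )
        assert t == TYPE_ES

    def test_intron_retention(self):
        assert self.classify_pair([(0, 400)], [(0, 100), (300, 400)]) == TYPE_IR

    def test_alternative_acceptor_plus_strand(self):
        assert self.classify_pair([(0, 100), (200, 300)], [(0, 100), (250, 300)]) == TYPE_AAS

    def test_alternative_donor_plus_strand(self):
        assert self.classify_pair([(0, 100), (200, 300)], [(0, 80), (200, 300)]) == TYPE_ADS

    def test_acceptor_donor_labels_swap_on_minus_strand(self):
        t = self.classify_pair([(0, 100), (200, 300)], [(0, 100), (250, 300)], strand="-")
        assert t == TYPE_ADS
        t = self.classify_pair([(0, 100), (200, 300)], [(0, 80), (200, 300)], strand="-")
        assert t == TYPE_AAS

    def test_mutually_exclusive_exons(self):
        t = self.classify_pair(
            [(0, 100), (200, 250), (400, 500)], [(0, 100), (300, 350), (400, 500)]
        )
        assert t == TYPE_MEE

    def test_overlapping_alternative_exons_are_complex(self):
        t = self.classify_pair(
            [(0, 100), (200, 260), (400, 500)], [(0, 100), (240, 300), (400, 500)]
        )
        assert t == TYPE_COMPLEX

    def test_double_retention_is_complex(self):
        t = self.classify_pair([(0, 500)], [(0, 100), (200, 300), (400, 500)])
        assert t == TYPE_COMPLEX


class TestEnumerateEvents:
    def test_reference_plus_skip_isoform_yields_one_es(self):
        a = tx("a", [(0, 100), (200, 300), (400, 500)])
        b = tx("b", [(0, 100), (400, 500)])
        events = enumerate_events(make_locus([a, b]))
        assert [e.type for e in events] == [TYPE_ES]
        assert events[0].isoform_pairs == [("a", "b")]

    def test_single_isoform_no_events(self):
        assert enumerate_events(make_locus([tx("a", [(0, 100), (200, 300)])])) == []

    def test_identical_event_deduplicated_across_pairs(self):
        a = tx("a", [(0, 100), (200, 300), (400, 500)])
        b = tx("b", [(0, 100), (400, 500)])
        c = tx("c", [(0, 100), (400, 520)])  # same skip, longer terminus
        events = enumerate_events(make_locus([a, b, c]))
        es = [e for e in events if e.type == TYPE_ES]
        assert len(es) == 1
        assert set(es[0].isoform_pairs) == {("a", "b"), ("a", "c")}

    def test_mee_demoted_when_an_isoform_contains_both_exons(self):
        a = tx("a", with_context([(0, 100), (200, 250), (400, 500)]))
        b = tx("b", with_context([(0, 100), (300, 350), (400, 500)]))
        both = tx("c", with_context([(0, 100), (200, 250), (300, 350), (400, 500)]))
        types = {e.type for e in enumerate_events(make_locus([a, b, both]))}
        assert TYPE_MEE not in types

    def test_member_order_invariance(self):
        rng = np.random.default_rng(3)
        for k in range(10):
            locus = random_locus(rng, locus_id=f"L{k}")
            fwd = enumerate_events(locus)
            locus.members = list(reversed(locus.members))
            rev = enumerate_events(locus)
            key = lambda e: (e.anchors, e.inclusion_sites, e.exclusion_sites, e.type)
            assert {key(e) for e in fwd} == {key(e) for e in rev}

    def test_matches_naive_oracle_on_random_loci(self):
        rng = np.random.default_rng(21)
        for k in range(100):
            locus = random_locus(rng, locus_id=f"L{k}")
            main = {
                (e.anchors, e.inclusion_sites, e.exclusion_sites, e.type)
                for e in enumerate_events(locus)
            }
            naive = {
                (e["anchors"], e["inclusion_sites"], e["exclusion_sites"], e["type"])
                for e in naive_enumerate_events(locus)
            }
            assert main == naive


class TestEventJunctions:
    def event_of(self, exons_a, exons_b, strand="+"):
        a = tx("a", with_context(exons_a), strand=strand)
        b = tx("b", with_context(exons_b), strand=strand)
        (ev,) = enumerate_events(make_locus([a, b]))
        return ev

    def test_es_junction_sets(self):
        ev = self.event_of([(0, 100), (200, 300), (400, 500)], [(0, 100), (400, 500)])
        assert ev.inclusion_junctions == {(100, 200), (300, 400)}
        assert ev.exclusion_junctions == {(100, 400)}
        assert event_multiplicities(ev) == (2, 1)

    def test_aas_junction_sets(self):
        ev = self.event_of([(0, 100), (200, 300)], [(0, 100), (250, 300)])
        assert ev.inclusion_junctions == {(100, 200)}
        assert ev.exclusion_junctions == {(100, 250)}
        assert event_multiplicities(ev) == (1, 1)

    def test_ir_spliced_intron_on_exclusion_side_only(self):
        ev = self.event_of([(0, 400)], [(0, 100), (300, 400)])
        assert ev.type == TYPE_IR
        assert ev.inclusion_junctions == frozenset()
        assert ev.exclusion_junctions == {(100, 300)}

    def test_mee_two_junctions_each_side(self):
        ev = self.event_of(
            [(0, 100), (200, 260), (400, 500)], [(0, 100), (300, 350), (400, 500)]
        )
        assert ev.type == TYPE_MEE
        assert len(ev.inclusion_junctions) == 2 and len(ev.exclusion_junctions) == 2

    def test_complex_event_unquantifiable(self):
        ev = self.event_of([(0, 500)], [(0, 100), (200, 300), (400, 500)])
        assert ev.type == TYPE_COMPLEX
        with pytest.raises(ValidationError, match="unquantifiable"):
            event_junctions(ev)
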