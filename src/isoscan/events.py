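"""Alternative-splicing event enumeration and classification.

Two isoforms of a locus are compared through their internal splice-site
chains.  A *bubble* is a maximal run of disagreeing splice structure
flanked by shared splice sites (or by transcript termini).  Each bubble is
classified into one of the five basic event types —

- ES  (exon skipping): one side carries complete exon(s) between a shared
  donor/acceptor anchor pair, the other side splices straight across;
- IR  (intron retention): one side reads through as uninterrupted exon,
  the other has exactly one intron strictly inside, with identical
  flanking exon boundaries;
- AAS (alternative acceptor site): the two sides differ only in the
  acceptor of one exon (strand-aware);
- ADS (alternative donor site): the sides differ only in a donor;
- MEE (mutually exclusive exons): each side holds exactly one exon between
  the anchors, the exons do not overlap, and no isoform of the locus
  contains both —

or into ``complex`` (anything else, e.g. combinations of basic patterns).

The *inclusion* form of an event is the side with more exonic bases
between the anchors; the other is the *exclusion* form.  Each form is
diagnosed by the intron set unique to it; the retained side of an IR event
has no diagnostic junction and is quantifiable only from separate
retention evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotate import Locus
from .model import Transcript, ValidationError

TYPE_ES = "ES"
TYPE_IR = "IR"
TYPE_MEE = "MEE"
TYPE_AAS = "AAS"
TYPE_ADS = "ADS"
TYPE_COMPLEX = "complex"

BASIC_TYPES = (TYPE_ES, TYPE_IR, TYPE_MEE, TYPE_AAS, TYPE_ADS)

# role of a splice site within a chain: even index = exon end (donor side
# on the + strand), odd index = exon start
_END, _START = "end", "start"


@dataclass
class Bubble:
    """A maximal region of structural disagreement between two isoforms."""

    chrom: str
    strand: str
    left: int | None          # shared splice site, or None for a terminus
    right: int | None
    left_role: str | None     # site role; None when termini differ
    right_role: str | None
    sites_a: tuple[int, ...]  # differing sites of isoform a, genomic order
    sites_b: tuple[int, ...]
    roles_a: tuple[str, ...]
    roles_b: tuple[str, ...]
    tx_a: Transcript = field(repr=False, default=None)
    tx_b: Transcript = field(repr=False, default=None)


@dataclass
class ASEvent:
    id: str
    locus_id: str
    type: str
    chrom: str
    strand: str
    anchors: tuple[int | None, int | None]
    inclusion_sites: tuple[int, ...]
    exclusion_sites: tuple[int, ...]
    inclusion_junctions: frozenset[tuple[int, int]]
    exclusion_junctions: frozenset[tuple[int, int]]
    isoform_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def gene_or_locus(self) -> str:
        return self.locus_id


def _roles(chain: tuple[int, ...]) -> dict[int, str]:
    return {v: (_END if i % 2 == 0 else _START) for i, v in enumerate(chain)}


def find_bubbles(a: Transcript, b: Transcript) -> list[Bubble]:
    """Locate all bubbles between two isoforms of one locus.

    Anchors are splice sites shared (with the same structural role) by both
    chains; because both chains are strictly increasing, shared sites align
    automatically.  Transcript termini bound the outermost bubbles; a
    terminus acts as a structural anchor only when both isoforms share its
    coordinate.
    """
    ca, cb = a.splice_chain, b.splice_chain
    if not ca and not cb:
        return []
    if ca == cb:
        return []
    roles_a, roles_b = _roles(ca), _roles(cb)
    shared = sorted(v for v in set(ca) & set(cb) if roles_a[v] == roles_b[v])

    boundaries: list[int | None] = [None, *shared, None]
    bubbles: list[Bubble] = []
    for L, R in zip(boundaries, boundaries[1:]):
        lo = L if L is not None else -1
        hi = R if R is not None else float("inf")
        sub_a = tuple(v for v in ca if lo < v < hi and v not in shared)
        sub_b = tuple(v for v in cb if lo < v < hi and v not in shared)
        if not sub_a and not sub_b:
            continue
        left_role = roles_a.get(L) if L is not None else (_START if a.start == b.start else None)
        right_role = roles_a.get(R) if R is not None else (_END if a.end == b.end else None)
        bubbles.append(
            Bubble(
                chrom=a.chrom,
                strand=a.strand,
                left=L,
                right=R,
                left_role=left_role,
                right_role=right_role,
                sites_a=sub_a,
                sites_b=sub_b,
                roles_a=tuple(roles_a[v] for v in sub_a),
                roles_b=tuple(roles_b[v] for v in sub_b),
                tx_a=a,
                tx_b=b,
            )
        )
    return bubbles


def _exonic_bases(t: Transcript, lo: int | None, hi: int | None) -> int:
    lo = lo if lo is not None else t.start
    hi = hi if hi is not None else t.end
    return sum(max(0, min(e.end, hi) - max(e.start, lo)) for e in t.exons)


def _is_complete_exon_run(roles: tuple[str, ...]) -> bool:
    """start,end repeated -> complete exon(s) between a donor and an acceptor."""
    if not roles or len(roles) % 2:
        return False
    return all(r == (_START if i % 2 == 0 else _END) for i, r in enumerate(roles))


def classify_bubble(bubble: Bubble) -> str:
    """Assign one of the five basic AS types (or ``complex``) to a bubble.

    MEE assignment here is pairwise; :func:`enumerate_events` additionally
    enforces the locus-wide condition that no isoform contains both exons.
    """
    if bubble.sites_a is None or bubble.sites_b is None:
        raise ValidationError("malformed bubble")
    sa, sb = bubble.sites_a, bubble.sites_b
    ra, rb = bubble.roles_a, bubble.roles_b
    lr, rr = bubble.left_role, bubble.right_role
    internal_anchors = lr is not None and rr is not None

    # single alternative site on each side: AAS / ADS (termini may differ)
    if len(sa) == 1 and len(sb) == 1 and ra == rb and sa != sb:
        site_role = ra[0]
        if site_role == _START:  # acceptor on +, donor on -
            return TYPE_AAS if bubble.strand == "+" else TYPE_ADS
        return TYPE_ADS if bubble.strand == "+" else TYPE_AAS

    if not internal_anchors:
        return TYPE_COMPLEX

    empty_side, full_roles = None, None
    if not sa and sb:
        empty_side, full_roles = "a", rb
    elif not sb and sa:
        empty_side, full_roles = "b", ra

    if empty_side is not None:
        # ES: donor..acceptor anchors, the full side holds complete exon(s)
        if lr == _END and rr == _START and _is_complete_exon_run(full_roles):
            return TYPE_ES
        # IR: anchors inside a shared exon; full side has exactly one intron
        if lr == _START and rr == _END and full_roles == (_END, _START):
            return TYPE_IR
        return TYPE_COMPLEX

    # MEE: one complete exon on each side between donor/acceptor anchors
    if (
        lr == _END
        and rr == _START
        and len(sa) == 2
        and len(sb) == 2
        and _is_complete_exon_run(ra)
        and _is_complete_exon_run(rb)
    ):
        exon_a, exon_b = (sa[0], sa[1]), (sb[0], sb[1])
        if min(exon_a[1], exon_b[1]) <= max(exon_a[0], exon_b[0]):
            return TYPE_MEE
    return TYPE_COMPLEX


def _introns_between(t: Transcript, lo: int | None, hi: int | None) -> set[tuple[int, int]]:
    lo = lo if lo is not None else t.start
    hi = hi if hi is not None else t.end
    return {(d, a) for d, a in t.introns if d >= lo and a <= hi}


def _bubble_event(bubble: Bubble, ev_type: str, locus_id: str) -> ASEvent:
    """Orient a bubble into inclusion/exclusion forms and collect junctions."""
    bases_a = _exonic_bases(bubble.tx_a, bubble.left, bubble.right)
    bases_b = _exonic_bases(bubble.tx_b, bubble.left, bubble.right)
    if bases_a != bases_b:
        a_is_inclusion = bases_a > bases_b
    else:
        # tie (possible for MEE): smaller leftmost coordinate is inclusion
        first_a = bubble.sites_a[0] if bubble.sites_a else bubble.left
        first_b = bubble.sites_b[0] if bubble.sites_b else bubble.left
        a_is_inclusion = (first_a, bubble.tx_a.id) <= (first_b, bubble.tx_b.id)
    inc_tx, exc_tx = (bubble.tx_a, bubble.tx_b) if a_is_inclusion else (bubble.tx_b, bubble.tx_a)
    inc_sites, exc_sites = (
        (bubble.sites_a, bubble.sites_b) if a_is_inclusion else (bubble.sites_b, bubble.sites_a)
    )
    inc_introns = _introns_between(inc_tx, bubble.left, bubble.right)
    exc_introns = _introns_between(exc_tx, bubble.left, bubble.right)
    return ASEvent(
        id="",
        locus_id=locus_id,
        type=ev_type,
        chrom=bubble.chrom,
        strand=bubble.strand,
        anchors=(bubble.left, bubble.right),
        inclusion_sites=inc_sites,
        exclusion_sites=exc_sites,
        inclusion_junctions=frozenset(inc_introns - exc_introns),
        exclusion_junctions=frozenset(exc_introns - inc_introns),
        isoform_pairs=[(inc_tx.id, exc_tx.id)],
    )


def enumerate_events(locus: Locus) -> list[ASEvent]:
    """All AS events among the isoforms of one (collapsed) locus.

    Every isoform pair is compared, bubbles are classified, and events with
    identical (anchors, inclusion chain, exclusion chain) are deduplicated
    across pairs.  MEE candidates are demoted to ``complex`` when some
    isoform of the locus contains both alternative exons.
    """
    members = locus.members
    events: dict[tuple, ASEvent] = {}
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if a.is_single_exon and b.is_single_exon:
                continue
            for bubble in find_bubbles(a, b):
                ev_type = classify_bubble(bubble)
                ev = _bubble_event(bubble, ev_type, locus.id)
                key = (ev.anchors, ev.inclusion_sites, ev.exclusion_sites)
                if key in events:
                    pair = ev.isoform_pairs[0]
                    if pair not in events[key].isoform_pairs:
                        events[key].isoform_pairs.append(pair)
                else:
                    events[key] = ev

    # locus-wide MEE condition: no isoform contains both alternative exons
    exon_sets = [{(e.start, e.end) for e in m.exons} for m in members]
    for ev in events.values():
        if ev.type == TYPE_MEE:
            exon_i = (ev.inclusion_sites[0], ev.inclusion_sites[1])
            exon_e = (ev.exclusion_sites[0], ev.exclusion_sites[1])
            if any(exon_i in s and exon_e in s for s in exon_sets):
                ev.type = TYPE_COMPLEX

    out = sorted(
        events.values(),
        key=lambda e: (
            e.chrom,
            e.anchors[0] if e.anchors[0] is not None else -1,
            e.anchors[1] if e.anchors[1] is not None else -1,
            e.inclusion_sites,
            e.exclusion_sites,
        ),
    )
    for k, ev in enumerate(out):
        ev.id = f"{locus.id}:e{k + 1}"
    return out


def event_junctions(
    ev: ASEvent,
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int]]]:
    """Diagnostic intron sets for the inclusion and exclusion forms.

    Complex events have no defined quantification and raise
    :class:`~isoscan.model.ValidationError`.
    """
    if ev.type == TYPE_COMPLEX:
        raise ValidationError(f"{ev.id}: unquantifiable event (complex)")
    return ev.inclusion_junctions, ev.exclusion_junctions


def event_multiplicities(ev: ASEvent) -> tuple[int, int]:
    """Effective junction multiplicities ``(l_I, l_S)`` for normalization.

    ES: (2, 1); AAS/ADS: (1, 1); MEE: (2, 2); IR: (1, 1) — the retained
    side of an IR event is counted from retention evidence, not junctions.
    """
    inc, exc = event_junctions(ev)
    return (max(1, len(inc)), max(1, len(exc)))
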