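"""Naive exhaustive re-implementation of AS-event enumeration.

This module re-derives event classification from first principles using
splice-site set differences and direct interval queries on exon lists,
deliberately sharing no logic with :mod:`isoscan.events` (which walks
role-annotated splice chains).  It exists to cross-validate the production
classifier: on any locus the two must agree event-for-event and
type-for-type.

It is quadratic and unoptimized by design; do not use it in pipelines.
"""

from __future__ import annotations

from .annotate import Locus
from .model import Transcript


def _site_role(t: Transcript, v: int) -> str | None:
    """Role of coordinate v in a transcript, by scanning exons."""
    for e in t.exons:
        if e.start == v:
            return "start"
        if e.end == v:
            return "end"
    return None


def _sites(t: Transcript) -> list[int]:
    out = []
    for k, e in enumerate(t.exons):
        if k > 0:
            out.append(e.start)
        if k < len(t.exons) - 1:
            out.append(e.end)
    return sorted(out)


def _exonic_bases(t: Transcript, lo: int, hi: int) -> int:
    return sum(max(0, min(e.end, hi) - max(e.start, lo)) for e in t.exons)


def _region_events(a: Transcript, b: Transcript) -> list[dict]:
    """Split the disagreement between two isoforms into regions and
    classify each by direct interval reasoning."""
    sites_a, sites_b = set(_sites(a)), set(_sites(b))
    if sites_a == sites_b:
        return []
    shared = sorted(
        v for v in sites_a & sites_b if _site_role(a, v) == _site_role(b, v)
    )
    events = []
    bounds = [None, *shared, None]
    for L, R in zip(bounds, bounds[1:]):
        lo = L if L is not None else min(a.start, b.start) - 1
        hi = R if R is not None else max(a.end, b.end) + 1
        da = sorted(v for v in sites_a - set(shared) if lo < v < hi)
        db = sorted(v for v in sites_b - set(shared) if lo < v < hi)
        if not da and not db:
            continue
        events.append(_classify_region(a, b, L, R, da, db))
    return events


def _complete_exons_between(t: Transcript, lo: float, hi: float):
    return [e for e in t.exons if lo < e.start and e.end < hi]


def _introns_between(t: Transcript, lo: float, hi: float):
    return [(d, ac) for d, ac in t.introns if d >= lo and ac <= hi]


def _classify_region(a, b, L, R, da, db) -> dict:
    strand = a.strand
    # structural anchors: shared sites, or coinciding termini
    left_role = _site_role(a, L) if L is not None else ("start" if a.start == b.start else None)
    right_role = _site_role(a, R) if R is not None else ("end" if a.end == b.end else None)
    ev_type = "complex"

    if len(da) == 1 and len(db) == 1:
        ra, rb = _site_role(a, da[0]), _site_role(b, db[0])
        if ra == rb:
            if ra == "start":
                ev_type = "AAS" if strand == "+" else "ADS"
            else:
                ev_type = "ADS" if strand == "+" else "AAS"

    if ev_type == "complex" and left_role is not None and right_role is not None:
        lo = L if L is not None else (a.start if a.start == b.start else None)
        hi = R if R is not None else (a.end if a.end == b.end else None)
        if lo is not None and hi is not None:
            empty, full = (a, b) if not da else ((b, a) if not db else (None, None))
            if empty is not None:
                full_exons = _complete_exons_between(full, lo, hi)
                full_sites = sorted(set(sum(([e.start, e.end] for e in full_exons), [])))
                full_diff = da if full is a else db
                if (
                    left_role == "end"
                    and right_role == "start"
                    and _introns_between(empty, lo, hi) == [(lo, hi)]
                    and full_exons
                    and full_sites == full_diff
                ):
                    ev_type = "ES"
                elif (
                    left_role == "start"
                    and right_role == "end"
                    and not _introns_between(empty, lo, hi)
                    and any(e.start <= lo and hi <= e.end for e in empty.exons)
                    and len(_introns_between(full, lo, hi)) == 1
                ):
                    ev_type = "IR"
            elif (
                left_role == "end"
                and right_role == "start"
                and len(da) == 2
                and len(db) == 2
            ):
                ex_a = _complete_exons_between(a, lo, hi)
                ex_b = _complete_exons_between(b, lo, hi)
                if (
                    len(ex_a) == 1
                    and len(ex_b) == 1
                    and [ex_a[0].start, ex_a[0].end] == da
                    and [ex_b[0].start, ex_b[0].end] == db
                    and (ex_a[0].end <= ex_b[0].start or ex_b[0].end <= ex_a[0].start)
                ):
                    ev_type = "MEE"

    # orient: inclusion = more exonic bases between the anchors
    lo_a = L if L is not None else a.start
    hi_a = R if R is not None else a.end
    lo_b = L if L is not None else b.start
    hi_b = R if R is not None else b.end
    bases_a = _exonic_bases(a, lo_a, hi_a)
    bases_b = _exonic_bases(b, lo_b, hi_b)
    if bases_a != bases_b:
        a_inc = bases_a > bases_b
    else:
        fa = da[0] if da else L
        fb = db[0] if db else L
        a_inc = (fa, a.id) <= (fb, b.id)
    inc_sites, exc_sites = (tuple(da), tuple(db)) if a_inc else (tuple(db), tuple(da))
    return {
        "anchors": (L, R),
        "type": ev_type,
        "inclusion_sites": inc_sites,
        "exclusion_sites": exc_sites,
    }


def naive_enumerate_events(locus: Locus) -> list[dict]:
    """All-pairs, set-difference-based event enumeration for one locus.

    Returns deduplicated event dicts with keys ``anchors``,
    ``inclusion_sites``, ``exclusion_sites``, ``type`` — directly
    comparable with :func:`isoscan.events.enumerate_events` output.
    """
    members = locus.members
    found: dict[tuple, dict] = {}
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = members[i], members[j]
            if len(a.exons) == 1 and len(b.exons) == 1:
                continue
            for ev in _region_events(a, b):
                key = (ev["anchors"], ev["inclusion_sites"], ev["exclusion_sites"])
                found.setdefault(key, ev)
    # locus-wide MEE condition, checked against raw exon memberships
    for ev in found.values():
        if ev["type"] == "MEE":
            inc = (ev["inclusion_sites"][0], ev["inclusion_sites"][1])
            exc = (ev["exclusion_sites"][0], ev["exclusion_sites"][1])
            for m in members:
                exon_set = {(e.start, e.end) for e in m.exons}
                if inc in exon_set and exc in exon_set:
                    ev["type"] = "complex"
                    break
    return sorted(
        found.values(),
        key=lambda e: (
            e["anchors"][0] if e["anchors"][0] is not None else -1,
            e["anchors"][1] if e["anchors"][1] is not None else -1,
            e["inclusion_sites"],
            e["exclusion_sites"],
        ),
    )
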