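"""Differential alternative splicing from junction counts.

The splicing level of an event is summarized per condition by the exon
inclusion ratio

    EI = (sum I / l_I) / (sum I / l_I + sum S / l_S)

where I and S are junction counts supporting the inclusion and exclusion
form, pooled over a condition's replicates, and (l_I, l_S) are the numbers
of diagnostic junctions of each form (effective-length normalization: an
inclusion read of an exon-skipping event supports two junctions, a
skipping read one).

Differential splicing between conditions A and B is tested per event with
a binomial likelihood-ratio test on the length-normalized counts: under H0
one shared inclusion probability generates all samples, under H1 each
condition has its own.  The statistic 2(l1 - l0) is referred to a
chi-square distribution with 1 df.  Events are called differentially
spliced (DAS) when |dEI| > 0.05 and Benjamini-Hochberg FDR < 0.05, both
strict inequalities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import ASEvent, TYPE_COMPLEX, TYPE_IR, event_junctions, event_multiplicities
from .model import JunctionTable

logger = logging.getLogger(__name__)


@dataclass
class EventCounts:
    """Per-sample inclusion/skipping junction counts for one event."""

    event_id: str
    event_type: str
    inclusion: dict[str, int]           # sample -> count
    skipping: dict[str, int]
    condition: dict[str, str]           # sample -> condition label
    l_inc: int = 1
    l_exc: int = 1
    gene_or_locus: str | None = None

    def samples_of(self, cond: str) -> list[str]:
        return sorted(s for s, c in self.condition.items() if c == cond)


@dataclass
class DASResult:
    event_id: str
    event_type: str
    ei_a: float
    ei_b: float
    delta_ei: float
    p_value: float
    fdr: float = float("nan")
    is_das: bool = False
    gene_or_locus: str | None = None

    @property
    def direction(self) -> str:
        return "increased" if self.delta_ei > 0 else ("decreased" if self.delta_ei < 0 else "none")


def estimate_ei(
    inclusion_counts, skipping_counts, l_inc: int = 1, l_exc: int = 1
) -> float | None:
    """Pooled exon-inclusion ratio for one condition; None when no counts."""
    i_tot = sum(inclusion_counts) / l_inc
    s_tot = sum(skipping_counts) / l_exc
    if i_tot + s_tot == 0:
        return None
    return i_tot / (i_tot + s_tot)


def _binom_loglik(i: np.ndarray, s: np.ndarray, q: float) -> float:
    q = min(max(q, 1e-300), 1 - 1e-16)
    return float(np.sum(i) * math.log(q) + np.sum(s) * math.log(1 - q))


def das_test(ec: EventCounts, cond_a: str = "A", cond_b: str = "B"):
    """Binomial LRT for condition-specific inclusion; returns (dEI, p) or None.

    Counts are first normalized by junction multiplicity so that one
    molecule contributes one effective count to its form.  None is returned
    (event skipped) when either condition has zero total evidence.
    """
    sa, sb = ec.samples_of(cond_a), ec.samples_of(cond_b)
    ia = np.array([ec.inclusion[s] for s in sa], float) / ec.l_inc
    sa_ = np.array([ec.skipping[s] for s in sa], float) / ec.l_exc
    ib = np.array([ec.inclusion[s] for s in sb], float) / ec.l_inc
    sb_ = np.array([ec.skipping[s] for s in sb], float) / ec.l_exc
    tot_a, tot_b = ia.sum() + sa_.sum(), ib.sum() + sb_.sum()
    if tot_a == 0 or tot_b == 0:
        return None
    ei_a = ia.sum() / tot_a
    ei_b = ib.sum() / tot_b
    q0 = (ia.sum() + ib.sum()) / (tot_a + tot_b)
    l0 = _binom_loglik(ia, sa_, q0) + _binom_loglik(ib, sb_, q0)
    l1 = _binom_loglik(ia, sa_, ei_a) + _binom_loglik(ib, sb_, ei_b)
    stat = max(0.0, 2.0 * (l1 - l0))
    p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return ei_b - ei_a, p, ei_a, ei_b


def call_das(
    tested: list[DASResult],
    delta_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> list[DASResult]:
    """Benjamini-Hochberg adjustment and strict-threshold DAS calling.

    ``is_das`` requires |dEI| strictly above ``delta_threshold`` and FDR
    strictly below ``fdr_threshold``.  Direction counts (increased vs
    decreased inclusion in condition B) are logged.
    """
    if not tested:
        return []
    pvals = np.array([r.p_value for r in tested])
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    n_up = n_down = 0
    for r, fdr in zip(tested, fdrs):
        r.fdr = float(fdr)
        r.is_das = abs(r.delta_ei) > delta_threshold and r.fdr < fdr_threshold
        if r.is_das:
            if r.delta_ei > 0:
                n_up += 1
            else:
                n_down += 1
    logger.info("call_das: %d DAS events (%d increased, %d decreased EI in B)",
                n_up + n_down, n_up, n_down)
    return tested


def quantify_events(
    events: list[ASEvent],
    junctions: JunctionTable,
    condition_map: dict[str, str],
    retention: JunctionTable | None = None,
) -> list[EventCounts]:
    """Build per-sample inclusion/skipping counts for quantifiable events.

    Complex events are excluded.  IR events have no diagnostic junction on
    the retained side; their inclusion evidence is looked up in the
    ``retention`` table (keyed by the retained intron) and IR events are
    skipped entirely when that table is absent.
    """
    out: list[EventCounts] = []
    samples = sorted(condition_map)
    n_skipped_ir = 0
    for ev in events:
        if ev.type == TYPE_COMPLEX:
            continue
        inc_j, exc_j = event_junctions(ev)
        l_inc, l_exc = event_multiplicities(ev)
        if ev.type == TYPE_IR:
            if retention is None:
                n_skipped_ir += 1
                continue
            # the retained intron IS the spliced form's diagnostic intron
            inc_counts = retention.sample_counts(ev.chrom, exc_j, ev.strand)
        else:
            inc_counts = junctions.sample_counts(ev.chrom, inc_j, ev.strand)
        exc_counts = junctions.sample_counts(ev.chrom, exc_j, ev.strand)
        out.append(
            EventCounts(
                event_id=ev.id,
                event_type=ev.type,
                inclusion={s: inc_counts.get(s, 0) for s in samples},
                skipping={s: exc_counts.get(s, 0) for s in samples},
                condition=dict(condition_map),
                l_inc=l_inc,
                l_exc=l_exc,
                gene_or_locus=ev.locus_id,
            )
        )
    if n_skipped_ir:
        logger.info("quantify_events: %d IR event(s) unquantified (no retention evidence)",
                    n_skipped_ir)
    return out


def run_das(
    counts: list[EventCounts],
    cond_a: str = "A",
    cond_b: str = "B",
    delta_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
) -> list[DASResult]:
    """Test every quantifiable event and apply the DAS decision rule."""
    tested: list[DASResult] = []
    n_skipped = 0
    for ec in counts:
        res = das_test(ec, cond_a, cond_b)
        if res is None:
            n_skipped += 1
            continue
        delta, p, ei_a, ei_b = res
        tested.append(
            DASResult(
                event_id=ec.event_id,
                event_type=ec.event_type,
                ei_a=ei_a,
                ei_b=ei_b,
                delta_ei=delta,
                p_value=p,
                gene_or_locus=ec.gene_or_locus,
            )
        )
    if n_skipped:
        logger.info("run_das: %d event(s) skipped for zero evidence in a condition", n_skipped)
    return call_das(tested, delta_threshold, fdr_threshold)


def das_results_frame(results: list[DASResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "type": r.event_type,
                "gene_or_locus": r.gene_or_locus,
                "EI_A": r.ei_a,
                "EI_B": r.ei_b,
                "delta_EI": r.delta_ei,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "is_das": r.is_das,
                "direction": r.direction,
            }
            for r in results
        ]
    )
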