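"""Synthetic-data generator: determinism, degenerate configs, sampling laws."""

import numpy as np
import pytest

from isoscan.annotation_io import write_annotation
from isoscan.simulate import (
    ConfigurationError,
    SimulationConfig,
    simulate_gene_counts,
    simulate_junction_counts,
    simulate_reads,
    simulate_reference,
)


class TestSimulateReference:
    def test_seeded_determinism_byte_identical_gtf(self, tmp_path):
        cfg = SimulationConfig(n_genes=10, seed=1)
        p1, p2 = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_annotation(simulate_reference(cfg), p1, "gtf")
        write_annotation(simulate_reference(cfg), p2, "gtf")
        assert p1.read_bytes() == p2.read_bytes()

    def test_single_exon_range_gives_single_exon_genes(self):
        ann = simulate_reference(SimulationConfig(n_genes=5, exon_count_range=(1, 1), seed=2))
        assert all(t.is_single_exon for t in ann.transcripts)

    def test_zero_genes(self):
        ann = simulate_reference(SimulationConfig(n_genes=0, novel_locus_count=0, fusion_count=0))
        assert ann.n_transcripts == 0

    def test_genes_do_not_overlap(self):
        ann = simulate_reference(SimulationConfig(n_genes=30, seed=3))
        spans = {}
        for gid in ann.genes:
            chrom, _, s, e = ann.gene_span(gid)
            spans.setdefault(chrom, []).append((s, e))
        for ivs in spans.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_isoforms_of_gene_share_an_exon(self):
        ann = simulate_reference(SimulationConfig(n_genes=20, seed=4))
        for txs in ann.genes.values():
            if len(txs) > 1:
                common = set.intersection(*({(e.start, e.end) for e in t.exons} for t in txs))
                assert common


class TestSimulateReads:
    def test_no_truncation_all_known_reads_match_reference_chains(self):
        cfg = SimulationConfig(n_genes=10, five_prime_truncation_prob=0.0, seed=5)
        ann = simulate_reference(cfg)
        reads, truth = simulate_reads(cfg, ann)
        ref_chains = {
            (t.chrom, t.strand, t.splice_chain, t.span) for t in ann.transcripts
        }
        for r in reads:
            if truth.true_class.get(r.read_id) == "known":
                assert (r.chrom, r.strand, r.splice_chain, r.span) in ref_chains

    def test_fusion_count_and_interchromosomal_fraction(self):
        cfg = SimulationConfig(
            n_genes=10, fusion_count=2, fusion_interchrom_fraction=1.0, seed=6
        )
        ann = simulate_reference(cfg)
        reads, truth = simulate_reads(cfg, ann)
        assert len(truth.true_fusion) == 2
        for rid, (ga, gb, inter) in truth.true_fusion.items():
            assert inter
            segs = [r for r in reads if r.read_id == rid]
            assert len({s.chrom for s in segs}) == 2

    def test_zero_rates_emit_only_known(self):
        cfg = SimulationConfig(
            n_genes=5, novel_isoform_rate=0.0, novel_locus_count=0, fusion_count=0, seed=7
        )
        ann = simulate_reference(cfg)
        _, truth = simulate_reads(cfg, ann)
        assert set(truth.true_class.values()) == {"known"}

    def test_every_read_is_labeled(self):
        cfg = SimulationConfig(n_genes=8, seed=8)
        ann = simulate_reference(cfg)
        reads, truth = simulate_reads(cfg, ann)
        read_ids = {r.read_id for r in reads}
        assert read_ids == set(truth.true_class)

    def test_injected_event_types_cover_all_five(self):
        cfg = SimulationConfig(n_genes=20, novel_isoform_rate=1.0, seed=9)
        ann = simulate_reference(cfg)
        _, truth = simulate_reads(cfg, ann)
        assert {e.type for e in truth.true_events.values()} == {"ES", "IR", "AAS", "ADS", "MEE"}


class TestSimulateJunctionCounts:
    def _truth(self, cfg):
        ann = simulate_reference(cfg)
        reads, truth = simulate_reads(cfg, ann)
        return reads, truth

    def test_full_inclusion_gives_zero_skipping(self):
        cfg = SimulationConfig(n_genes=5, ei_null=1.0, das_event_fraction=0.0, seed=10)
        reads, truth = self._truth(cfg)
        junctions, _ = simulate_junction_counts(cfg, truth)
        for ev in truth.true_events.values():
            if ev.type == "IR":
                continue
            for d, a in ev.exclusion_junctions:
                counts = junctions.sample_counts(ev.chrom, [(d, a)], ev.strand)
                assert all(c == 0 for c in counts.values())

    def test_observed_ei_converges_to_truth_at_high_depth(self):
        cfg = SimulationConfig(
            n_genes=30, junction_depth=10_000, das_event_fraction=0.0, seed=11
        )
        reads, truth = self._truth(cfg)
        junctions, retention = simulate_junction_counts(cfg, truth)
        eis = []
        for ev in truth.true_events.values():
            table = retention if ev.type == "IR" else junctions
            inc_key = ev.exclusion_junctions if ev.type == "IR" else ev.inclusion_junctions
            inc = table.sample_counts(ev.chrom, sorted(inc_key)[:1], ev.strand)
            exc = junctions.sample_counts(ev.chrom, sorted(ev.exclusion_junctions)[:1], ev.strand)
            i, s = sum(inc.values()), sum(exc.values())
            if ev.type != "IR":
                eis.append(i / (i + s))
        assert abs(np.mean(eis) - 0.5) < 0.02

    def test_same_seed_identical_table(self):
        cfg = SimulationConfig(n_genes=5, seed=12)
        reads, truth = self._truth(cfg)
        j1, r1 = simulate_junction_counts(cfg, truth, reads)
        j2, r2 = simulate_junction_counts(cfg, truth, reads)
        assert j1.df.equals(j2.df) and r1.df.equals(r2.df)

    def test_invalid_depth_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(junction_depth=0)


class TestSimulateGeneCounts:
    def test_near_poisson_mean_recovery(self):
        cfg = SimulationConfig(
            n_genes=40, expr_dispersion=1e-13, de_gene_fraction=0.0, seed=13,
            n_replicates_per_condition=13,
        )
        ann = simulate_reference(cfg)
        counts = simulate_gene_counts(cfg, ann)
        # 40 genes x 26 samples > 1000 draws at the configured mean
        assert counts.size >= 1000
        assert abs(counts.to_numpy().mean() - cfg.expr_mean) / cfg.expr_mean < 0.05

    def test_null_gene_condition_means_match(self):
        cfg = SimulationConfig(n_genes=10, de_gene_fraction=0.0, seed=14)
        ann = simulate_reference(cfg)
        from isoscan.simulate import GroundTruth
        truth = GroundTruth()
        simulate_gene_counts(cfg, ann, truth)
        assert all(v == 0.0 for v in truth.true_log2fc.values())
        assert not truth.true_deg

    def test_seed_fixed_identical_matrix(self):
        cfg = SimulationConfig(n_genes=10, seed=15)
        ann = simulate_reference(cfg)
        assert simulate_gene_counts(cfg, ann).equals(simulate_gene_counts(cfg, ann))

    def test_unknown_effect_gene_rejected(self):
        cfg = SimulationConfig(n_genes=3, de_log2fc_effects=[("nope", 2.0)], seed=16)
        ann = simulate_reference(cfg)
        with pytest.raises(ConfigurationError):
            simulate_gene_counts(cfg, ann)
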