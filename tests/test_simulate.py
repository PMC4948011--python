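"""Ground-truth generator: geometry, determinism, accounting."""

import numpy as np
import pytest

from synqtl import filtering, simulate, synteny
from synqtl.model import ChainParams
from synqtl.simulate import (
    MapConfig, NoiseConfig, QTLConfig, SimConfig, _Anc,
    apply_inversion, apply_translocation, apply_transposition,
    random_history_config, simulate_genome_pair, simulate_map_and_qtl,
)


def _anc(chrom, start, end, strand="+"):
    return _Anc("x", "Q01", start, end, chrom, start, end, strand)


class TestEventGeometry:
    def test_inversion_is_an_involution(self):
        anchors = [_anc("T01", s, s + 100) for s in range(0, 10_000, 500)]
        ref = [(a.t_start, a.t_end, a.strand) for a in anchors]
        apply_inversion(anchors, "T01", 1000, 6000)
        moved = [(a.t_start, a.t_end, a.strand) for a in anchors]
        assert moved != ref
        apply_inversion(anchors, "T01", 1000, 6000)
        assert [(a.t_start, a.t_end, a.strand) for a in anchors] == ref

    def test_inversion_reverses_order_and_flips_strand(self):
        anchors = [_anc("T01", 1000, 1100), _anc("T01", 2000, 2100)]
        apply_inversion(anchors, "T01", 500, 2500)
        assert anchors[0].t_start > anchors[1].t_start
        assert {a.strand for a in anchors} == {"-"}

    def test_transposition_preserves_lengths_and_moves_segment(self):
        anchors = [_anc("T01", s, s + 100) for s in (1000, 2000, 3000, 8000, 9000)]
        fs, fe = apply_transposition(anchors, "T01", 900, 3200, 9500)
        assert (fs, fe) == (9500 - 2300, 9500)
        for a in anchors:
            assert a.t_end - a.t_start == 100
        # relative order inside the moved segment is preserved
        seg = sorted(a.t_start for a in anchors[:3])
        assert seg == [s + (9500 - 3200) for s in (1000, 2000, 3000)]

    def test_translocation_conserves_arm_geometry(self):
        a1 = [_anc("T01", s, s + 100) for s in (1000, 30_000_000, 40_000_000)]
        a2 = [_anc("T02", s, s + 100) for s in (2000, 35_000_000, 45_000_000)]
        apply_translocation(a1 + a2, "T01", 25_000_000, "T02", 28_000_000)
        assert [a.t_chrom for a in a1] == ["T01", "T02", "T02"]
        assert [a.t_chrom for a in a2] == ["T02", "T01", "T01"]
        # distal offsets preserved relative to the new breakpoint
        assert a1[1].t_start == 28_000_000 + (30_000_000 - 25_000_000)


class TestGenomePair:
    def test_null_simulation_is_identity(self):
        cfg = SimConfig(seed=1, n_inversions=0, n_translocations=0,
                        n_transpositions=0, n_duplications=0,
                        anchors_per_chrom=50, noise=NoiseConfig.none())
        sim = simulate_genome_pair(cfg)
        assert sim.truth.signatures == []
        for h in sim.hits:
            assert h.query_chrom.replace("Q", "T") == h.target_chrom
            assert h.query_start == h.target_start
        params = ChainParams()
        res = synteny.chain_anchors(sim.hits, params)
        a = synteny.assign_chromosome_orthology(sim.hits)
        assert synteny.call_rearrangements(res.blocks, a.mapping, params) == []

    def test_single_planted_inversion_recovered(self):
        cfg = SimConfig(seed=2, n_inversions=1, n_translocations=0,
                        n_transpositions=0, n_duplications=0,
                        noise=NoiseConfig.none())
        sim = simulate_genome_pair(cfg)
        (sig,) = sim.truth.signatures
        params = ChainParams()
        res = synteny.chain_anchors(sim.hits, params)
        minus = [b for b in res.blocks if b.orientation == "-"]
        assert len(minus) == 1
        a = synteny.assign_chromosome_orthology(sim.hits)
        calls = synteny.call_rearrangements(res.blocks, a.mapping, params)
        assert [c.kind for c in calls] == ["inversion"]
        assert calls[0].target_chrom == sig.target_chrom

    def test_seed_determinism(self):
        h0 = simulate_genome_pair(SimConfig(seed=0)).hits
        h0b = simulate_genome_pair(SimConfig(seed=0)).hits
        h1 = simulate_genome_pair(SimConfig(seed=1)).hits
        assert h0 == h0b
        assert h0 != h1

    def test_anchor_accounting_reconciles(self):
        cfg = SimConfig(seed=6)
        sim = simulate_genome_pair(cfg)
        assert len(sim.hits) == \
            sim.n_placed - sim.n_deleted + sim.n_paralog_copies + sim.n_spurious

    def test_too_many_event_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_inversions=10, n_translocations=2)

    def test_oversized_event_span_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(max_event_span_bp=20_000_000, chrom_length_bp=50_000_000)

    def test_random_history_event_counts_in_range(self):
        for seed in range(30):
            cfg = random_history_config(seed)
            total = cfg.n_inversions + cfg.n_translocations + \
                cfg.n_transpositions + cfg.n_duplications
            assert 3 <= total <= 8
            used = cfg.n_inversions + cfg.n_transpositions + cfg.n_duplications \
                + 2 * cfg.n_translocations
            assert used <= cfg.n_chrom

    def test_low_quality_hits_fail_the_cds_filter(self):
        cfg = SimConfig(seed=3, noise=NoiseConfig(0, 0, 0, 0, low_quality_rate=0.2))
        sim = simulate_genome_pair(cfg)
        kept = filtering.filter_hits(sim.hits, filtering.PRESETS["tocds-peg"])
        frac = len(kept) / len(sim.hits)
        assert 0.7 < frac < 0.9  # roughly the complement of the contaminant rate


class TestMapAndQTL:
    def test_linear_map_projects_exactly(self):
        from synqtl.projection import project_qtl
        cfg = SimConfig(seed=4, map=MapConfig(rate_function="linear"),
                        qtl=QTLConfig(count=10))
        ms = simulate_map_and_qtl(cfg)
        for qtl, truth in zip(ms.qtls, ms.truth):
            r = project_qtl(qtl, ms.anchors, mode="local_rate")
            assert abs(r.physical.peak_bp - truth.peak_bp) <= 1
            width = r.physical.end_bp - r.physical.start_bp
            true_width = truth.end_bp - truth.start_bp
            assert abs(width - true_width) <= 1

    def test_environment_cis_average_to_true_ci(self):
        ms = simulate_map_and_qtl(SimConfig(seed=4))
        from synqtl.projection import average_environment_ci
        for qtl in ms.qtls:
            lo, hi = average_environment_ci(qtl)
            assert lo == pytest.approx(qtl.ci_lo_cM)
            assert hi == pytest.approx(qtl.ci_hi_cM)

    def test_sigmoid_piecewise_beats_local_rate(self):
        from synqtl.projection import project_qtl
        cfg = SimConfig(seed=8, map=MapConfig(rate_function="sigmoid"),
                        qtl=QTLConfig(count=100))
        ms = simulate_map_and_qtl(cfg)
        pw = lr = 0.0
        for qtl, truth in zip(ms.qtls, ms.truth):
            rp = project_qtl(qtl, ms.anchors, mode="piecewise")
            rl = project_qtl(qtl, ms.anchors, mode="local_rate")
            pw += abs(rp.physical.start_bp - truth.start_bp) \
                + abs(rp.physical.end_bp - truth.end_bp)
            lr += abs(rl.physical.start_bp - truth.start_bp) \
                + abs(rl.physical.end_bp - truth.end_bp)
        assert pw < lr

    def test_zero_orthologous_fraction_yields_no_pairs(self):
        from synqtl.orthology import TraitEquivalence, find_orthologous_pairs
        from synqtl.projection import project_all
        cfg = SimConfig(seed=5, qtl=QTLConfig(count=10, fraction_orthologous=0.0))
        ms = simulate_map_and_qtl(cfg)
        assert ms.other_species_qtls == []
        projected = [r.physical for r in project_all(ms.qtls, ms.anchors)]
        traits = TraitEquivalence(ms.trait_map)
        report = find_orthologous_pairs(projected, [], traits, 10_000_000)
        assert report.pairs == []
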