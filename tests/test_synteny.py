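"""Anchor chaining, block orientation and rearrangement classification."""

import numpy as np
import pytest

from synqtl import simulate, synteny, filtering
from synqtl.model import AnchorHit, ChainParams
from synqtl.synteny import (
    assign_chromosome_orthology, block_orientation_kendall, call_rearrangements,
    chain_anchors, dotplot_table,
)


def anchor(qc, qpos, tc, tpos, length=1000, qid=None, strand="+"):
    return AnchorHit(
        query_id=qid or f"a{qc}_{qpos}_{tpos}",
        query_chrom=qc, query_start=float(qpos), query_end=float(qpos + length),
        target_chrom=tc, target_start=int(tpos), target_end=int(tpos + length),
        strand=strand, identity=0.95, coverage=0.9,
        aligned_length=length, match_bp=int(0.95 * length),
        mismatch_bp=length - int(0.95 * length),
    )


def colinear_run(qc, tc, n, start=0, spacing=100_000, reverse_query=False):
    hits = []
    for i in range(n):
        qpos = start + (n - 1 - i) * spacing if reverse_query else start + i * spacing
        hits.append(anchor(qc, qpos, tc, start + i * spacing, qid=f"{qc}{tc}{i}"))
    return hits


class TestOrthologyAssignment:
    def test_plurality_wins(self):
        hits = colinear_run("T01", "P01", 10) + colinear_run("T08", "P01", 2, start=5_000_000)
        a = assign_chromosome_orthology(hits)
        assert a.mapping == {"P01": "T01"}
        assert a.counts.loc["P01", "T01"] == 10

    def test_empty(self):
        a = assign_chromosome_orthology([])
        assert a.mapping == {} and a.same_chromosome_fraction == 0.0

    def test_simulated_pairing_recovered_through_noise(self):
        cfg = simulate.SimConfig(
            seed=5, n_inversions=0, n_translocations=0, n_transpositions=0,
            n_duplications=0, anchors_per_chrom=100,
            noise=simulate.NoiseConfig(spurious_hit_rate=0.05, missing_anchor_rate=0,
                                       paralog_rate=0, positional_jitter_bp=0,
                                       low_quality_rate=0))
        sim = simulate.simulate_genome_pair(cfg)
        a = assign_chromosome_orthology(sim.hits)
        assert a.mapping == {f"T{i:02d}": f"Q{i:02d}" for i in range(1, 13)}
        assert a.same_chromosome_fraction > 0.9


class TestChaining:
    def test_colinear_run_chains_into_one_forward_block(self):
        hits = colinear_run("Q01", "T01", 10)
        res = chain_anchors(hits, ChainParams())
        (block,) = res.blocks
        assert block.orientation == "+" and block.anchor_count == 10
        assert res.dropped == []

    def test_reversed_query_gives_minus_block(self):
        hits = colinear_run("Q01", "T01", 10, reverse_query=True)
        (block,) = chain_anchors(hits, ChainParams()).blocks
        assert block.orientation == "-" and block.anchor_count == 10
        assert block_orientation_kendall(block) == "-"

    def test_large_gap_splits_into_planted_blocks(self):
        params = ChainParams(max_gap_bp=1_000_000, min_anchors=3)
        run1 = colinear_run("Q01", "T01", 10, start=0)
        run2 = colinear_run("Q01", "T01", 10, start=900_000 + 2 * params.max_gap_bp)
        res = chain_anchors(run1 + run2, params)
        assert len(res.blocks) == 2
        got = [sorted(a.query_id for a in b.anchors) for b in res.blocks]
        assert got == [sorted(h.query_id for h in run1), sorted(h.query_id for h in run2)]

    def test_anchor_conservation(self, rng):
        from conftest import random_hits
        hits = random_hits(rng, 400, n_chrom=3, with_query=True)
        res = chain_anchors(hits, ChainParams(max_gap_bp=2_000_000))
        in_blocks = sum(b.anchor_count for b in res.blocks)
        assert in_blocks + len(res.dropped) == len(hits)
        seen = {id(a) for b in res.blocks for a in b.anchors} | {id(a) for a in res.dropped}
        assert len(seen) == len(hits)

    def test_kendall_orientation_agrees_with_direction_rule(self):
        cfg = simulate.SimConfig(seed=2, noise=simulate.NoiseConfig.none())
        sim = simulate.simulate_genome_pair(cfg)
        res = chain_anchors(sim.hits, ChainParams())
        for b in res.blocks:
            k = block_orientation_kendall(b)
            if k is not None:
                assert k == b.orientation


def _call_pipeline(hits, params=None):
    params = params or ChainParams()
    res = chain_anchors(hits, params)
    a = assign_chromosome_orthology(hits)
    return call_rearrangements(res.blocks, a.mapping, params)


class TestCallRules:
    def _chromosome_with_inversion(self, inv_span):
        spacing = 100_000
        n_inv = max(3, inv_span // spacing)
        hits = colinear_run("Q01", "T01", 30, start=0, spacing=spacing)
        inv_start = 31 * spacing
        for i in range(n_inv):
            qpos = inv_start + (n_inv - 1 - i) * spacing
            hits.append(anchor("Q01", qpos, "T01", inv_start + i * spacing,
                               qid=f"inv{i}", strand="-"))
        tail_start = inv_start + (n_inv + 1) * spacing
        hits += colinear_run("Q01", "T01", 30, start=tail_start, spacing=spacing)
        return hits

    def test_minus_block_in_plus_chromosome_is_inversion(self):
        calls = _call_pipeline(self._chromosome_with_inversion(1_200_000))
        kinds = [c.kind for c in calls]
        assert kinds == ["inversion"]
        assert calls[0].orientation == "-"

    def test_span_rule_excludes_small_inversion(self):
        hits = self._chromosome_with_inversion(400_000)
        assert _call_pipeline(hits, ChainParams(min_span_bp=500_000)) == []
        calls = _call_pipeline(hits, ChainParams(min_span_bp=300_000))
        assert [c.kind for c in calls] == ["inversion"]

    def test_translocated_block_called(self):
        hits = (colinear_run("Q01", "T01", 40) + colinear_run("Q02", "T02", 40)
                + colinear_run("Q02", "T01", 8, start=8_000_000))
        calls = _call_pipeline(hits)
        assert [(c.kind, c.query_chrom, c.target_chrom) for c in calls] == \
            [("translocation", "Q02", "T01")]

    def test_min_span_monotonicity(self):
        cfg = simulate.random_history_config(17, noise=simulate.NoiseConfig.none())
        sim = simulate.simulate_genome_pair(cfg)
        hits = sim.hits
        res = chain_anchors(hits, ChainParams())
        a = assign_chromosome_orthology(hits)
        spans = [2_000_000, 1_000_000, 500_000, 300_000, 100_000]
        sizes = []
        prev_set = None
        for s in spans:
            calls = call_rearrangements(res.blocks, a.mapping, ChainParams(min_span_bp=s))
            cur = {(c.kind, c.target_chrom, c.target_start) for c in calls}
            if prev_set is not None:
                assert prev_set <= cur  # lowering the span never removes a call
            prev_set = cur
            sizes.append(len(cur))
        assert sizes == sorted(sizes)

    def test_calls_invariant_under_genome_swap(self):
        # inversions stay inversions, translocations stay translocations,
        # when query and target roles are exchanged
        cfg = simulate.SimConfig(seed=23, n_inversions=3, n_translocations=2,
                                 n_transpositions=0, n_duplications=0,
                                 noise=simulate.NoiseConfig.none())
        sim = simulate.simulate_genome_pair(cfg)
        calls = _call_pipeline(sim.hits)
        swapped = [
            AnchorHit(
                query_id=h.query_id, query_chrom=h.target_chrom,
                query_start=float(h.target_start), query_end=float(h.target_end),
                target_chrom=h.query_chrom, target_start=int(h.query_start),
                target_end=int(h.query_end), strand=h.strand,
                identity=h.identity, coverage=h.coverage,
                aligned_length=h.aligned_length, match_bp=h.match_bp,
                mismatch_bp=h.mismatch_bp,
            )
            for h in sim.hits
        ]
        swapped_calls = _call_pipeline(swapped)

        def kinds(calls):
            return sorted(c.kind for c in calls)

        assert kinds(calls) == kinds(swapped_calls)


class TestDotplot:
    def test_table_holds_midpoints(self):
        hits = [anchor("Q01", 100, "T01", 500, length=100),
                anchor("Q01", 1000, "T01", 2000, length=100),
                anchor("Q02", 5, "T02", 7, length=10)]
        table = dotplot_table(hits)
        assert len(table) == 3
        assert list(table.x) == [h.target_mid for h in hits]
        assert list(table.y) == [h.query_mid for h in hits]

    def test_highlighted_points_are_exactly_called_anchors(self):
        cfg = simulate.SimConfig(seed=4, n_inversions=2, n_translocations=0,
                                 n_transpositions=0, n_duplications=0,
                                 noise=simulate.NoiseConfig.none())
        sim = simulate.simulate_genome_pair(cfg)
        params = ChainParams()
        res = chain_anchors(sim.hits, params)
        a = assign_chromosome_orthology(sim.hits)
        calls = call_rearrangements(res.blocks, a.mapping, params)
        table = dotplot_table(sim.hits, calls)
        called_ids = {anc.query_id for c in calls for b in c.blocks for anc in b.anchors}
        flagged = set()
        for h, flag in zip(sim.hits, table.in_call):
            if flag:
                flagged.add(h.query_id)
        assert flagged == called_ids

    def test_inverted_block_has_negative_local_slope(self):
        cfg = simulate.SimConfig(seed=4, n_inversions=1, n_translocations=0,
                                 n_transpositions=0, n_duplications=0,
                                 noise=simulate.NoiseConfig.none())
        sim = simulate.simulate_genome_pair(cfg)
        params = ChainParams()
        res = chain_anchors(sim.hits, params)
        a = assign_chromosome_orthology(sim.hits)
        calls = call_rearrangements(res.blocks, a.mapping, params)
        (inv,) = [c for c in calls if c.kind == "inversion"]
        pts = sorted((anc.target_mid, anc.query_mid) for b in inv.blocks
                     for anc in b.anchors)
        diffs = np.diff([y for _, y in pts])
        assert (diffs < 0).all()

    def test_dotplot_writes_panels_and_tsv(self, tmp_path):
        hits = colinear_run("Q01", "T01", 5)
        table, files = synteny.dotplot(hits, str(tmp_path) + "/")
        assert (tmp_path / "points.tsv").exists()
        assert any(f.endswith(".png") for f in files)
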