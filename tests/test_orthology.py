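"""QTL orthology: trait equivalence, pairing, clustering."""

import numpy as np
import pytest

from synqtl import simulate
from synqtl.model import PhysicalQTL
from synqtl.orthology import (
    TraitEquivalence, cluster_qtl, filter_major, find_orthologous_pairs,
)


def q(qid, chrom, start, end, trait="fruit length", species="eggplant", pve=15.0):
    return PhysicalQTL(qid, trait, species, chrom, start, end, (start + end) // 2, pve)


TRAITS = TraitEquivalence({"fruit length": ["fruit size"], "flowering": []})


class TestTraitEquivalence:
    def test_symmetric_closure_and_self_relation(self):
        assert TRAITS.related("fruit length", "fruit size")
        assert TRAITS.related("fruit size", "fruit length")
        assert TRAITS.related("flowering", "flowering")
        assert not TRAITS.related("fruit length", "flowering")

    def test_known(self):
        assert TRAITS.known("fruit size") and not TRAITS.known("prickliness")


class TestFilterMajor:
    def test_threshold_inclusive(self):
        keep = q("a", "P01", 0, 10, pve=10.0)
        drop = q("b", "P01", 0, 10, pve=9.9)
        assert filter_major([keep, drop]) == [keep]

    def test_empty(self):
        assert filter_major([]) == []


class TestPairs:
    def test_overlapping_related_traits_pair(self):
        a = q("a", "P01", 10_000_000, 12_000_000, "fruit length")
        b = q("b", "P01", 11_500_000, 14_000_000, "fruit size", species="pepper")
        report = find_orthologous_pairs([a], [b], TRAITS, proximity_bp=1_000_000)
        assert report.pairs == [(a, b)]

    def test_unrelated_traits_do_not_pair(self):
        a = q("a", "P01", 10_000_000, 12_000_000, "fruit length")
        b = q("b", "P01", 11_500_000, 14_000_000, "flowering", species="pepper")
        assert find_orthologous_pairs([a], [b], TRAITS, 1_000_000).pairs == []

    def test_unknown_trait_skipped_and_counted(self):
        a = q("a", "P01", 0, 1_000_000, "prickliness")
        b = q("b", "P01", 0, 1_000_000, "fruit length", species="pepper")
        report = find_orthologous_pairs([a], [b], TRAITS, 1_000_000)
        assert report.pairs == [] and report.n_skipped_unknown_trait == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        traits = ["fruit length", "fruit size", "flowering"]

        def rand_set(species, n):
            out = []
            for i in range(n):
                s = int(rng.integers(0, 40_000_000))
                out.append(q(f"{species}{i}", f"P{int(rng.integers(1, 4)):02d}",
                             s, s + int(rng.integers(100_000, 3_000_000)),
                             traits[int(rng.integers(3))], species))
            return out

        A, B = rand_set("egg", 50), rand_set("pep", 50)
        prox = 1_000_000
        got = {(a.qtl_id, b.qtl_id)
               for a, b in find_orthologous_pairs(A, B, TRAITS, prox).pairs}
        expected = set()
        for a in A:
            for b in B:
                if a.chrom != b.chrom or not TRAITS.related(a.trait, b.trait):
                    continue
                gap = max(a.start_bp, b.start_bp) - min(a.end_bp, b.end_bp)
                if gap <= prox:
                    expected.add((a.qtl_id, b.qtl_id))
        assert got == expected

    def test_pair_set_monotone_in_proximity(self):
        rng = np.random.default_rng(12)
        A = [q(f"a{i}", "P01", s := int(rng.integers(0, 30_000_000)), s + 500_000)
             for i in range(20)]
        B = [q(f"b{i}", "P01", s := int(rng.integers(0, 30_000_000)), s + 500_000,
               species="pepper") for i in range(20)]
        prev = set()
        for prox in (0, 100_000, 1_000_000, 10_000_000):
            cur = {(a.qtl_id, b.qtl_id)
                   for a, b in find_orthologous_pairs(A, B, TRAITS, prox).pairs}
            assert prev <= cur
            prev = cur


class TestClusters:
    def test_three_overlapping_form_one_orthologous_cluster(self):
        a1 = q("a1", "P01", 0, 2_000_000)
        a2 = q("a2", "P01", 500_000, 2_500_000)
        b1 = q("b1", "P01", 1_000_000, 3_000_000, species="pepper")
        (c,) = cluster_qtl([a1, a2], [b1], merge_gap_bp=1_000_000)
        assert c.orthologous and c.n_members == 3
        assert (c.start_bp, c.end_bp) == (0, 3_000_000)  # hull of members

    def test_distant_qtl_stay_separate(self):
        a = q("a", "P01", 0, 1_000_000)
        b = q("b", "P01", 10_000_000, 11_000_000, species="pepper")
        clusters = cluster_qtl([a], [b], merge_gap_bp=1_000_000)
        assert len(clusters) == 2
        assert all(not c.orthologous for c in clusters)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_connected_components_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        qtls = [q(f"x{i}", f"P{int(rng.integers(1, 3)):02d}",
                  s := int(rng.integers(0, 20_000_000)),
                  s + int(rng.integers(100_000, 2_000_000)),
                  species="eggplant" if i % 2 else "pepper")
                for i in range(60)]
        gap = 500_000
        A = [x for x in qtls if x.species == "eggplant"]
        B = [x for x in qtls if x.species == "pepper"]
        clusters = cluster_qtl(A, B, merge_gap_bp=gap)
        got = sorted(sorted(m.qtl_id for m in c.members_a + c.members_b)
                     for c in clusters)
        # brute force: union-find over the pairwise gap predicate
        n = len(qtls)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                a, b = qtls[i], qtls[j]
                if a.chrom != b.chrom:
                    continue
                if max(a.start_bp, b.start_bp) - min(a.end_bp, b.end_bp) <= gap:
                    parent[find(i)] = find(j)
        comps = {}
        for i in range(n):
            comps.setdefault(find(i), []).append(qtls[i].qtl_id)
        expected = sorted(sorted(v) for v in comps.values())
        assert got == expected

    def test_every_pair_lands_in_one_cluster(self):
        rng = np.random.default_rng(77)
        A = [q(f"a{i}", "P02", s := int(rng.integers(0, 20_000_000)), s + 1_000_000)
             for i in range(15)]
        B = [q(f"b{i}", "P02", s := int(rng.integers(0, 20_000_000)), s + 1_000_000,
               species="pepper") for i in range(15)]
        pairs = find_orthologous_pairs(A, B, TRAITS, 1_000_000).pairs
        clusters = cluster_qtl(A, B, merge_gap_bp=1_000_000)
        where = {m.qtl_id: c.cluster_id for c in clusters
                 for m in c.members_a + c.members_b}
        for a, b in pairs:
            assert where[a.qtl_id] == where[b.qtl_id]

    def test_member_counts_reconcile(self):
        cs = simulate.simulate_qtl_clusters(seed=3)
        clusters = cluster_qtl(cs.qtls_a, cs.qtls_b, merge_gap_bp=1_000_000)
        total = sum(c.n_members for c in clusters)
        assert total == len(cs.qtls_a) + len(cs.qtls_b)

    def test_planted_two_species_and_single_species_clusters_recovered(self):
        cs = simulate.simulate_qtl_clusters(n_two_species=8, n_one_species=6, seed=1)
        clusters = cluster_qtl(cs.qtls_a, cs.qtls_b, merge_gap_bp=1_000_000)
        assert len(clusters) == 14
        assert sum(1 for c in clusters if c.orthologous) == 8
        assert sum(1 for c in clusters if not c.orthologous) == 6
        # membership matches the planted assignment exactly
        for c in clusters:
            planted = {cs.assignments[m.qtl_id] for m in c.members_a + c.members_b}
            assert len(planted) == 1
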