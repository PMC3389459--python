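"""Median construction, small phylogeny, WGD handling, block validation."""

import numpy as np
import pytest

from orthopath.genomes import Chromosome, Genome
from orthopath.homology import COLUMNS, PairwiseHomologyTable
from orthopath.pathgroups import (
    block_integrity,
    doubled_distance,
    fractionation_correction,
    hidden_cycle_search,
    median,
    reinsert_single_copy_runs,
    restricted_distance,
    single_copy_runs,
    small_phylogeny,
)
from orthopath.dcj import dcj_distance, dcj_distance_orders
from orthopath.simulate import SimulationConfig, apply_random_dcj, random_genome, simulate_tree

import pandas as pd

from helpers import make_genome, orders_of
from oracles import enumerate_genomes, exhaustive_median_total


class TestMedian:
    def test_identical_inputs_reproduce_the_genome(self):
        g = make_genome("A", (1, 2, 3))
        M, dists = median(g, make_genome("B", (1, 2, 3)), make_genome("C", (1, 2, 3)))
        assert dists == (0, 0, 0)
        assert orders_of(M) == [(("1", 1), ("2", 1), ("3", 1))]

    def test_two_against_one_snaps_to_the_majority(self):
        g1 = make_genome("A", (1, 2, 3))
        g2 = make_genome("B", (1, -2, 3))
        g3 = make_genome("C", (1, -2, 3))
        M, dists = median(g1, g2, g3)
        assert sum(dists) == dcj_distance(orders_of(g1), orders_of(g2))

    def test_disjoint_inversions_resolved_independently(self):
        g1 = make_genome("A", (-2, -1, 3, 4, 5, 6))
        g2 = make_genome("B", (1, 2, -4, -3, 5, 6))
        g3 = make_genome("C", (1, 2, 3, 4, -6, -5))
        M, dists = median(g1, g2, g3)
        assert sum(dists) == 3
        assert orders_of(M) == [tuple((str(i), 1) for i in range(1, 7))]

    def test_empty_content_is_an_error(self):
        g = make_genome("A", (1,))
        with pytest.raises(ValueError, match="empty"):
            median(g, g, g, content=set())

    def test_bounds_sandwich_on_random_instances(self):
        """max pairwise distance <= median total <= best single-genome total."""
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            base = random_genome(n, min(n, int(rng.integers(1, 3))), int(rng.integers(2**31)))
            gs = [
                apply_random_dcj(base, int(rng.integers(0, 4)), int(rng.integers(2**31)))[0]
                for _ in range(3)
            ]
            ods = [orders_of(g) for g in gs]
            M, dists = median(*gs, by="gene")
            total = sum(dists)
            pairwise = [
                dcj_distance_orders(ods[i], ods[j])
                for i, j in ((0, 1), (0, 2), (1, 2))
            ]
            assert total >= max(pairwise)
            upper = min(
                sum(dcj_distance_orders(ods[i], ods[j]) for j in range(3))
                for i in range(3)
            )
            assert total <= upper

    def test_matches_exhaustive_optimum_on_seeded_instances(self):
        """>= 90% equality with the exhaustive median, never below it."""
        cands = {
            n: enumerate_genomes([f"g{i}" for i in range(1, n + 1)])
            for n in (3, 4, 5)
        }
        eq = tot = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = [3, 4, 5][seed % 3]
            base = random_genome(n, 1, int(rng.integers(2**31)))
            gs = [
                apply_random_dcj(base, int(rng.integers(1, 3)), int(rng.integers(2**31)))[0]
                for _ in range(3)
            ]
            ods = [orders_of(g) for g in gs]
            opt = exhaustive_median_total(ods, cands[n])
            _M, dists = median(*gs, by="gene")
            total = sum(dists)
            assert total >= opt
            tot += 1
            eq += total == opt
        assert eq / tot >= 0.9


class TestUnequalContent:
    def test_median_on_unequal_content_uses_majority_content(self):
        g1 = make_genome("A", (1, 2, 3, 4))
        g2 = make_genome("B", (1, 2, 4))
        g3 = make_genome("C", (1, 2, 3))
        M, dists = median(g1, g2, g3)
        assert M.gene_ids() == {"1", "2", "3", "4"}
        assert sum(dists) == 0  # deletions only, no rearrangement

    def test_hidden_cycle_through_absent_gene(self):
        # leaf (1 2 3) with 2 absent from the ancestor: extending the path
        # blocked at 2 reveals the closable pair (1_h, 3_t)
        leaf = make_genome("L", (1, 2, 3))
        assert hidden_cycle_search(
            (("1", "h"), ("2", "t")), {"2"}, leaf, by="gene"
        ) == 1

    def test_no_absent_genes_no_extra_cycle(self):
        leaf = make_genome("L", (1, 2, 3))
        assert hidden_cycle_search(
            (("1", "h"), ("2", "t")), set(), leaf, by="gene"
        ) == 0

    def test_absent_run_reaching_cap(self):
        # leaf (1 2): 2 absent, extension from 2_t runs off the chromosome
        # end; a single mixed endpoint closes nothing
        leaf = make_genome("L", (1, 2))
        assert hidden_cycle_search(
            (("1", "h"), ("2", "t")), {"2"}, leaf, by="gene"
        ) == 0
        # both endpoints extend to caps: telomere-to-telomere closure
        leaf2 = make_genome("L", (2, 1, 3))
        assert hidden_cycle_search(
            (("2", "h"), ("3", "t")), {"2", "3"}, leaf2, by="gene"
        ) == 1

    def test_restricted_distance_matches_manual_restriction(self):
        g1 = make_genome("A", (1, 2, 3, 4, 5))
        g2 = make_genome("B", (1, 3, -5))
        manual = dcj_distance(
            g1.restricted({"1", "3", "5"}), g2, by="gene"
        )
        assert restricted_distance(g1, g2, by1="gene", by2="gene") == manual


def _wgd_genome(name, *chroms):
    """Chromosomes of (family, copy, sign) triples."""
    cs = []
    assignment = {}
    for c in chroms:
        genes = []
        for fam, copy, sign in c:
            gid = f"{fam}{copy}"
            genes.append((gid, sign))
            assignment[gid] = str(fam)
        cs.append(Chromosome(tuple(genes)))
    return Genome(name, cs, is_wgd_descendant=True).with_orthosets(assignment)


class TestWgd:
    def test_unrearranged_doubled_genome_has_halving_distance_zero(self):
        T = _wgd_genome("T", [("a", "x", 1), ("b", "x", 1)], [("a", "y", 1), ("b", "y", 1)])
        half = Genome("H", [Chromosome((("a", 1), ("b", 1)))]).with_orthosets(
            {"a": "a", "b": "b"}
        )
        assert doubled_distance(T, half) == 0

    def test_one_inversion_after_doubling_costs_one(self):
        T = _wgd_genome("T", [("a", "x", 1), ("b", "x", -1)], [("a", "y", 1), ("b", "y", 1)])
        half = Genome("H", [Chromosome((("a", 1), ("b", 1)))]).with_orthosets(
            {"a": "a", "b": "b"}
        )
        assert doubled_distance(T, half) == 1

    def test_doubled_distance_matches_brute_force_on_two_genes(self):
        """Greedy copy pairing equals the minimum over explicit labelings."""
        half = Genome("H", [Chromosome((("a", 1), ("b", 1)))]).with_orthosets(
            {"a": "a", "b": "b"}
        )
        half_orders = [((("a"), 1), (("b"), 1))]
        rng = np.random.default_rng(3)
        for _ in range(20):
            doubled = Genome(
                "T",
                [Chromosome((("a1", 1), ("b1", 1))), Chromosome((("a2", 1), ("b2", 1)))],
                is_wgd_descendant=True,
            )
            T, _ = apply_random_dcj(doubled, int(rng.integers(0, 3)), int(rng.integers(2**31)))
            T = Genome(
                "T", T.chromosomes, is_wgd_descendant=True
            ).with_orthosets({"a1": "a", "a2": "a", "b1": "b", "b2": "b"})
            greedy = doubled_distance(T, half)
            # brute force: try both copy labelings of the doubled ancestor
            best = None
            t_orders = [
                tuple((gid, s) for gid, s in c.genes) for c in T.chromosomes
            ]
            for swap_a in (False, True):
                for swap_b in (False, True):
                    lab = {
                        "a1": "a2" if swap_a else "a1",
                        "a2": "a1" if swap_a else "a2",
                        "b1": "b2" if swap_b else "b1",
                        "b2": "b1" if swap_b else "b2",
                    }
                    anc = [
                        ((("a1"), 1), (("b1"), 1)),
                        ((("a2"), 1), (("b2"), 1)),
                    ]
                    relabelled = [
                        tuple((lab[g], s) for g, s in c) for c in t_orders
                    ]
                    d = dcj_distance_orders(relabelled, anc)
                    best = d if best is None else min(best, d)
            assert greedy == best

    def test_single_copy_gene_excluded_from_halving(self):
        T = _wgd_genome(
            "T",
            [("1", "x", 1), ("q", "", 1), ("2", "x", 1)],
            [("1", "y", 1), ("2", "y", 1)],
        )
        half = Genome("H", [Chromosome((("1", 1), ("2", 1)))]).with_orthosets(
            {"1": "1", "2": "2"}
        )
        assert doubled_distance(T, half) == 0  # 'q' plays no role


class TestFractionation:
    def test_short_runs_need_no_correction(self):
        T = _wgd_genome(
            "T",
            [("1", "x", 1), ("u", "", 1), ("v", "", 1), ("2", "x", 1)],
            [("1", "y", 1), ("2", "y", 1), ("w", "", 1)],
        )
        assert [r["length"] for r in single_copy_runs(T)] == [2, 1]
        assert fractionation_correction(T) == 0.0

    def test_correction_formula_on_fixed_runs(self):
        # runs of lengths 4, 5 and 9 -> 4/3 + 5/3 + 3 = 6.0
        chroms = []
        fams = 0
        runs = []
        for length in (4, 5, 9):
            runs.append([(f"s{fams + i}", "", 1) for i in range(length)])
            fams += length
        T = _wgd_genome(
            "T",
            [("d1", "x", 1)] + runs[0] + [("d2", "x", 1)] + runs[1] + [("d3", "x", 1)],
            [("d1", "y", 1), ("d2", "y", 1), ("d3", "y", 1)] + runs[2],
        )
        assert sorted(r["length"] for r in single_copy_runs(T)) == [4, 5, 9]
        assert fractionation_correction(T) == pytest.approx(6.0)

    def test_single_run_of_six(self):
        run = [(f"s{i}", "", 1) for i in range(6)]
        T = _wgd_genome(
            "T", [("d", "x", 1)] + run, [("d", "y", 1)]
        )
        assert fractionation_correction(T) == pytest.approx(2.0)

    def test_non_wgd_genome_is_an_error(self):
        with pytest.raises(ValueError):
            fractionation_correction(make_genome("A", (1, 2)))


class TestReinsertion:
    def test_run_inserted_next_to_both_copies(self):
        T = _wgd_genome(
            "T",
            [("1", "x", 1), ("a", "", 1), ("2", "x", 1)],
            [("1", "y", 1), ("2", "y", 1)],
        )
        half = Genome("H", [Chromosome((("1", 1), ("2", 1)))]).with_orthosets(
            {"1": "1", "2": "2"}
        )
        A = reinsert_single_copy_runs(half, T)
        seqs = {tuple(os for os, _s in c) for c in _orthoset_orders(A)}
        assert seqs == {("1", "a", "2")}
        assert len(A.chromosomes) == 2

    def test_consolidation_merges_runs_from_both_copies(self):
        T = _wgd_genome(
            "T",
            [("g", "x", 1), ("a", "", 1), ("b", "", 1)],
            [("g", "y", 1), ("c", "", 1)],
        )
        half = Genome("H", [Chromosome((("g", 1),))]).with_orthosets({"g": "g"})
        A = reinsert_single_copy_runs(half, T)
        for chrom in _orthoset_orders(A):
            oss = [os for os, _s in chrom]
            assert oss[0] == "g"  # run placed after g in both halves
            assert set(oss[1:]) == {"a", "b", "c"}

    def test_no_single_copy_genes_changes_nothing_but_doubles(self):
        T = _wgd_genome("T", [("1", "x", 1)], [("1", "y", 1)])
        half = Genome("H", [Chromosome((("1", 1),))]).with_orthosets({"1": "1"})
        A = reinsert_single_copy_runs(half, T)
        assert len(A) == 2
        assert A.is_wgd_descendant

    def test_insertion_does_not_change_the_doubled_distance(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            base = random_genome(8, 2, int(rng.integers(2**31)))
            from orthopath.simulate import simulate_wgd

            T = simulate_wgd(base, fractionation_loss=0.4, seed=int(rng.integers(2**31)))
            T = T.with_orthosets({g: g.rsplit(".", 1)[0] for g in T.gene_ids()})
            dup = sorted(
                {o for o in (x.orthoset_id for x in T.genes.values())
                 if sum(1 for y in T.genes.values() if y.orthoset_id == o) == 2}
            )
            half = Genome(
                "H", [Chromosome(tuple((d, 1) for d in dup))]
            ).with_orthosets({d: d for d in dup})
            before = doubled_distance(T, half)
            A = reinsert_single_copy_runs(half, T)
            # re-derive the half ancestor from A and verify distance is kept
            assert doubled_distance(T, half) == before


def _orthoset_orders(g):
    out = []
    for c in g.chromosomes:
        out.append(tuple((g.genes[gid].orthoset_id, s) for gid, s in c.genes))
    return out


class TestSmallPhylogeny:
    def test_identical_leaves_give_zero_total(self):
        from orthopath.trees import read_tree

        tree = read_tree("((A,B),(C,D));")
        leaves = {
            name: make_genome(name, (1, 2, 3)).with_orthosets(
                {"1": "1", "2": "2", "3": "3"}
            )
            for name in "ABCD"
        }
        res = small_phylogeny(tree, leaves)
        assert res.total == 0
        for anc in res.ancestors.values():
            assert anc.orthoset_ids() == {"1", "2", "3"}

    def test_reconstruction_beats_generating_scenario_on_small_tree(self):
        cfg = SimulationConfig(
            n_genes=20, n_chromosomes=1, ops_per_branch=1, seed=21,
            tree="((A,B),(C,D));",
        )
        res = simulate_tree(cfg)
        out = small_phylogeny(res.tree, res.leaf_genomes)
        assert out.total <= res.total_ops

    def test_sweep_totals_never_increase(self):
        cfg = SimulationConfig(n_genes=100, n_chromosomes=3, dn_ratio=0.15, seed=2,
                               tree="(G1,(G2,(G3,(G4,(G5,G6)))));")
        res = simulate_tree(cfg)
        out = small_phylogeny(res.tree, res.leaf_genomes)
        assert out.sweep_totals == sorted(out.sweep_totals, reverse=True)

    def test_unequal_content_with_wgd_completes(self):
        """Gene loss plus a WGD descendant: red edges are dropped from
        branches lacking the gene, and the solver must never revisit a
        consumed extremity through such a branch."""
        cfg = SimulationConfig(
            n_genes=80, n_chromosomes=3, dn_ratio=0.1, seed=17, loss_rate=0.1,
            tree="(G1,(G2[&WGD],(G3,(G4,(G5,G6)))));",
        )
        res = simulate_tree(cfg)
        out = small_phylogeny(res.tree, res.leaf_genomes)
        assert out.sweep_totals == sorted(out.sweep_totals, reverse=True)
        for anc in out.ancestors.values():
            ids = [gid for c in anc.chromosomes for gid, _s in c.genes]
            assert len(ids) == len(set(ids))

    def test_ancestor_fragments_partition_content(self):
        cfg = SimulationConfig(n_genes=60, n_chromosomes=2, dn_ratio=0.1, seed=4,
                               tree="((A,B),(C,D));")
        res = simulate_tree(cfg)
        out = small_phylogeny(res.tree, res.leaf_genomes)
        for anc in out.ancestors.values():
            ids = [gid for c in anc.chromosomes for gid, _s in c.genes]
            assert len(ids) == len(set(ids))


class TestBlockIntegrity:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=COLUMNS)
        return PairwiseHomologyTable("A", "B", df)

    def _rows(self, genes, block="b1"):
        return [
            ("A", g, "c1", i + 1, "+", "B", g, "c1", i + 1, "+", block)
            for i, g in enumerate(genes)
        ]

    def test_intact_block_reports_zero(self):
        table = self._table(self._rows(["1", "2", "3", "4", "5"]))
        anc = make_genome("M", (1, 2, 3, 4, 5)).with_orthosets(
            {str(i): str(i) for i in range(1, 6)}
        )
        (rec,) = block_integrity(table, anc, {str(i): str(i) for i in range(1, 6)})
        assert rec["breaks"] == 0
        assert rec["displacement"] == 0.0

    def test_reversed_block_still_intact(self):
        table = self._table(self._rows(["1", "2", "3", "4", "5"]))
        anc = make_genome("M", (-5, -4, -3, -2, -1)).with_orthosets(
            {str(i): str(i) for i in range(1, 6)}
        )
        (rec,) = block_integrity(table, anc, {str(i): str(i) for i in range(1, 6)})
        assert rec["breaks"] == 0
        assert rec["displacement"] == 0.0

    def test_internal_two_gene_inversion(self):
        table = self._table(self._rows(["1", "2", "3", "4", "5"]))
        anc = make_genome("M", (1, -3, -2, 4, 5)).with_orthosets(
            {str(i): str(i) for i in range(1, 6)}
        )
        (rec,) = block_integrity(table, anc, {str(i): str(i) for i in range(1, 6)})
        assert rec["breaks"] == 2
        assert rec["displacement"] <= 1.0

    def test_block_split_across_fragments_counts_a_break(self):
        table = self._table(self._rows(["1", "2", "3", "4"]))
        anc = make_genome("M", (1, 2), (3, 4), fragments=True).with_orthosets(
            {str(i): str(i) for i in range(1, 5)}
        )
        (rec,) = block_integrity(table, anc, {str(i): str(i) for i in range(1, 5)})
        assert rec["breaks"] >= 1
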