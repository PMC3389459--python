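"""Orthology-set construction: graph building, greedy resolution, tangles."""

import random

import networkx as nx
import numpy as np
import pytest

from orthopath.homology import PairwiseHomologyTable, COLUMNS
from orthopath.omg import (
    build_homology_graph,
    decompose_tangle,
    omg,
    prefilter_components,
    resolve_component,
    transitive_closure,
)
from orthopath.simulate import SimulationConfig, simulate_tree
from orthopath.trees import read_tree

from helpers import family_component_instance
from oracles import exhaustive_partition_optimum, set_objective

import pandas as pd


def _table(genome_a, genome_b, rows):
    df = pd.DataFrame(
        [
            (genome_a, ga, "c1", i + 1, "+", genome_b, gb, "c1", i + 1, "+", bid)
            for i, (ga, gb, bid) in enumerate(rows)
        ],
        columns=COLUMNS,
    )
    return PairwiseHomologyTable(genome_a, genome_b, df)


class TestHomologyGraph:
    def test_block_size_filter(self):
        t = _table("A", "B", [(f"a{i}", f"b{i}", "blk") for i in range(5)])
        assert build_homology_graph([t], min_block_size=5).number_of_edges() == 5
        assert build_homology_graph([t], min_block_size=6).number_of_edges() == 0

    def test_shared_gene_is_one_vertex(self):
        t1 = _table("A", "B", [("x", "b1", "k1")])
        t2 = _table("A", "C", [("x", "c1", "k2")])
        H = build_homology_graph([t1, t2])
        assert H.degree(("A", "x")) == 2

    def test_closure_makes_cliques_and_is_idempotent(self):
        P = nx.Graph([("x", "y"), ("y", "z"), ("u", "v")])
        C = transitive_closure(P)
        assert C.has_edge("x", "z")
        assert not C.has_edge("x", "u")
        assert nx.utils.graphs_equal(C, transitive_closure(C))


class TestPrefilter:
    TREE = read_tree("(A,(B,(C,(D,(E,F)))));")

    def test_adjacent_genomes_retained(self):
        H = nx.Graph([((("A"), "a1"), (("B"), "b1"))])
        H = nx.Graph([(("A", "a1"), ("B", "b1"))])
        kept = prefilter_components(H, self.TREE)
        assert kept.number_of_edges() == 1

    def test_remote_two_gene_component_removed(self):
        H = nx.Graph([(("A", "a1"), ("F", "f1"))])
        kept = prefilter_components(H, self.TREE)
        assert kept.number_of_nodes() == 0

    def test_three_gene_component_spanning_distant_genomes_retained(self):
        H = nx.Graph([(("A", "a1"), ("F", "f1")), (("F", "f1"), ("E", "e1"))])
        kept = prefilter_components(H, self.TREE)
        assert kept.number_of_edges() == 2

    def test_unknown_genome_is_an_error(self):
        H = nx.Graph([(("A", "a1"), ("Z", "z1"))])
        with pytest.raises(ValueError, match="Z"):
            prefilter_components(H, self.TREE)


class TestResolveComponent:
    def test_paralogy_pair_splits_off_singleton(self):
        G = nx.Graph([(("X", "x"), ("Y", "y1")), (("X", "x"), ("Y", "y2"))])
        sets = sorted(resolve_component(G), key=len)
        assert [len(s) for s in sets] == [1, 2]
        assert ("X", "x") in max(sets, key=len)

    def test_clean_component_untouched(self):
        G = nx.Graph([(("A", "a"), ("B", "b")), (("B", "b"), ("C", "c"))])
        (s,) = resolve_component(G)
        assert len(s) == 3

    def test_wgd_allowance_keeps_both_copies(self):
        G = nx.Graph(
            [(("grape", "g"), ("poplar", "p1")), (("grape", "g"), ("poplar", "p2"))]
        )
        (s,) = resolve_component(G, wgd_genomes={"poplar"})
        assert len(s) == 3

    def test_transitive_paralogy_is_resolved(self):
        # x1(X) - y(Y) - z(Z) - x2(X): compliant star by star, but the
        # closure would put two X genes in one orthology set
        G = nx.Graph(
            [
                (("X", "x1"), ("Y", "y")),
                (("Y", "y"), ("Z", "z")),
                (("Z", "z"), ("X", "x2")),
            ]
        )
        sets = resolve_component(G)
        for s in sets:
            genomes = [g for g, _ in s]
            assert len(genomes) == len(set(genomes))

    def test_favours_unbalanced_split(self):
        # a 6-clique with genome A represented twice can be cut into a
        # 5-set plus a singleton (25 + 1 closure edges worth) or two
        # triples (9 + 9): the objective prefers the unbalanced split
        nodes = [("A", "a1"), ("B", "b"), ("C", "c"), ("D", "d"), ("E", "e"), ("A", "a2")]
        G = nx.complete_graph(len(nodes))
        G = nx.relabel_nodes(G, dict(enumerate(nodes)))
        G.remove_edge(("A", "a1"), ("A", "a2"))
        sets = sorted(resolve_component(G), key=len)
        assert [len(s) for s in sets] == [1, 5]
        assert set_objective([sorted(s) for s in sets]) == exhaustive_partition_optimum(G)

    def test_greedy_matches_exhaustive_on_seeded_components(self):
        """>= 90% optimality, never above, on 100 seeded noisy components."""
        rng = random.Random(0)
        eq = tot = 0
        for _ in range(100):
            G = family_component_instance(rng)
            for comp in nx.connected_components(G):
                sub = G.subgraph(comp)
                sets = resolve_component(sub)
                val = set_objective([sorted(s) for s in sets])
                opt = exhaustive_partition_optimum(sub)
                assert val <= opt
                tot += 1
                eq += val == opt
        assert tot >= 100
        assert eq / tot >= 0.9

    def test_never_beats_optimum_on_dense_random_graphs(self):
        """Dense uniform-random components: output stays paralogy-free and
        never exceeds the exhaustive optimum (quality degrades gracefully
        outside the sparse-noise operating regime)."""
        rng = random.Random(7)
        genomes = ["A", "B", "C", "D"]
        for _ in range(60):
            nv = rng.randrange(4, 9)
            nodes = list(
                dict.fromkeys((genomes[rng.randrange(4)], f"g{i}") for i in range(nv))
            )
            G = nx.Graph()
            G.add_nodes_from(nodes)
            while not nx.is_connected(G) or G.number_of_edges() < len(nodes) - 1:
                u, v = rng.sample(nodes, 2)
                if u[0] != v[0]:
                    G.add_edge(u, v)
                if G.number_of_edges() >= 10:
                    break
            if not nx.is_connected(G):
                continue
            sets = resolve_component(G)
            for s in sets:
                gs = [g for g, _ in s]
                assert len(gs) == len(set(gs))
            assert set_objective(
                [sorted(s) for s in sets]
            ) <= exhaustive_partition_optimum(G)


class TestTangles:
    def test_star_extracted_whole(self):
        star = nx.star_graph(200)
        star = nx.relabel_nodes(
            star, {i: (f"G{i % 5}", f"g{i}") for i in star.nodes}
        )
        pieces = decompose_tangle(star, 100)
        assert len(pieces) == 1  # hub plus its immediate homologs

    def test_small_component_returned_intact(self):
        G = nx.path_graph(50)
        G = nx.relabel_nodes(G, {i: (f"G{i % 5}", f"g{i}") for i in G.nodes})
        assert len(decompose_tangle(G, 100)) == 1

    def test_large_component_split_covers_all_vertices(self):
        rng = random.Random(3)
        G = nx.Graph()
        nodes = [(f"G{i % 6}", f"g{i}") for i in range(150)]
        for i in range(149):
            G.add_edge(nodes[i], nodes[i + 1])
        for _ in range(100):
            u, v = rng.sample(nodes, 2)
            if u[0] != v[0]:
                G.add_edge(u, v)
        pieces = decompose_tangle(G, 100)
        assert len(pieces) >= 2
        covered = set()
        for p in pieces:
            covered |= set(p.nodes)
        assert covered == set(nodes)


class TestOmgPipeline:
    def test_empty_tables_give_empty_output(self):
        tree = read_tree("((A,B),(C,D));")
        assert omg([], tree) == []

    def test_zero_noise_recovers_families_exactly(self):
        cfg = SimulationConfig(
            n_genes=60, n_chromosomes=3, dn_ratio=0.1, seed=42,
            tree="(G1,(G2,(G3,G4)));",
        )
        res = simulate_tree(cfg)
        sets = omg(res.tables, res.tree)
        truth = {frozenset(v) for v in res.families.values() if len(v) >= 2}
        assert {s.genes for s in sets} == truth

    def test_noisy_output_paralogy_free_and_mostly_intact(self):
        cfg = SimulationConfig(
            n_genes=80, n_chromosomes=3, dn_ratio=0.1, seed=11, noise_rate=0.05,
            tree="(G1,(G2,(G3,(G4,(G5,G6)))));",
        )
        res = simulate_tree(cfg)
        sets = omg(res.tables, res.tree)
        for s in sets:
            genomes = [g for g, _ in s.genes]
            assert len(genomes) == len(set(genomes))
        truth = {frozenset(v) for v in res.families.values() if len(v) >= 2}
        intact = len(truth & {s.genes for s in sets})
        assert intact / len(truth) >= 0.95

    def test_min_block_size_monotone(self):
        cfg = SimulationConfig(
            n_genes=60, n_chromosomes=3, dn_ratio=0.1, seed=13, noise_rate=0.05,
            tree="(G1,(G2,(G3,G4)));",
        )
        res = simulate_tree(cfg)
        edges = [
            build_homology_graph(res.tables, mbs).number_of_edges()
            for mbs in (1, 2, 3, 5)
        ]
        assert edges == sorted(edges, reverse=True)
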