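"""Shared builders for the test suite."""

from __future__ import annotations

import random

from orthopath.genomes import Chromosome, Genome
from orthopath.trees import PhyloTree


def make_genome(name: str, *chroms, wgd: bool = False, fragments: bool = False) -> Genome:
    """Genome from int tuples: ``make_genome("A", (1, -2), (3,))``."""
    cs = [
        Chromosome(
            tuple((str(abs(g)), 1 if g > 0 else -1) for g in c),
            is_fragment=fragments,
        )
        for c in chroms
    ]
    return Genome(name, cs, is_wgd_descendant=wgd)


def orders_of(g: Genome):
    return [tuple(c.genes) for c in g.chromosomes]


def random_unrooted_tree(rng: random.Random, n_leaves: int) -> PhyloTree:
    """Random unrooted binary tree with leaves L1..Ln."""
    adj = {"M1": {"L1", "L2", "L3"}, "L1": {"M1"}, "L2": {"M1"}, "L3": {"M1"}}
    mi = 1
    for k in range(4, n_leaves + 1):
        edges = sorted({tuple(sorted((a, b))) for a in adj for b in adj[a]})
        a, b = edges[rng.randrange(len(edges))]
        mi += 1
        m, leaf = f"M{mi}", f"L{k}"
        adj[a].discard(b)
        adj[b].discard(a)
        adj[a].add(m)
        adj[b].add(m)
        adj[m] = {a, b, leaf}
        adj[leaf] = {m}
    return PhyloTree(adj)


def family_component_instance(rng):
    """Two true orthology families (cliques) with dropped and spurious
    edges: the component structure pooled pairwise syntenies produce."""
    import networkx as nx

    genomes = ["A", "B", "C", "D"]
    k = rng.randrange(2, 5)
    fams, nodes = [], []
    for f in range(2):
        fam = [(g, f"f{f}{g}") for g in rng.sample(genomes, k)]
        fams.append(fam)
        nodes += fam
    G = nx.Graph()
    G.add_nodes_from(nodes)
    for fam in fams:
        for i in range(len(fam)):
            for j in range(i + 1, len(fam)):
                G.add_edge(fam[i], fam[j])
    for e in list(G.edges):  # dropped homologies (families stay connected)
        if rng.random() < 0.15:
            G.remove_edge(*e)
            if not all(nx.is_connected(G.subgraph(f)) for f in fams if len(f) > 1):
                G.add_edge(*e)
    for _ in range(rng.randrange(1, 4)):  # spurious paralogy edges
        u, v = rng.sample(nodes, 2)
        if u[0] != v[0]:
            G.add_edge(u, v)
    return G
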