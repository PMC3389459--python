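"""Multi-genome orthology sets from pairwise homologies (the OMG step).

Pairwise synteny-block homologies are pooled into a homology graph whose
vertices are genes (identified by ``(genome, gene)``) and whose edges are
the reported cross-genome homologies.  Orthology is transitive, so every
connected component should ideally be one orthology set with at most one
gene per genome (two per WGD descendant).  Components violating that bound
contain spurious paralogy; they are resolved by greedily deleting edges,
one at a time, so that the surviving components decompose into
paralogy-free cliques.

The objective driving each deletion is F(E) = sum_v c(v), where c(v)
counts the distinct genomes represented in the star of v within the
transitive closure of the remaining graph (a WGD-descendant genome may
contribute up to two genes).  Ties are broken by minimizing
F+ = sum_v (nu(v) - c(v)), the residual paralogy load, and then by the
lexicographically smallest edge.  Maximizing F favours splitting a
conflicted component into one large and one small piece rather than two
equal halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx

from .homology import PairwiseHomologyTable
from .trees import PhyloTree

__all__ = [
    "GeneKey",
    "OrthologySet",
    "build_homology_graph",
    "transitive_closure",
    "prefilter_components",
    "decompose_tangle",
    "resolve_component",
    "omg",
    "orthoset_assignment",
]

GeneKey = tuple[str, str]  # (genome name, gene id)

TANGLE_THRESHOLD = 100  # components are "very rarely more than 100" genes


@dataclass(frozen=True)
class OrthologySet:
    """Genes across genomes descending from one ancestral gene."""

    id: str
    genes: frozenset  # of GeneKey

    def genomes(self) -> set[str]:
        return {g for g, _ in self.genes}

    def genes_in(self, genome: str) -> list[str]:
        return sorted(g for gm, g in self.genes if gm == genome)


def build_homology_graph(
    tables: Iterable[PairwiseHomologyTable], min_block_size: int = 1
) -> nx.Graph:
    """Pool pairwise homologies from sufficiently large blocks.

    Vertices are exactly the endpoints of surviving edges; genes whose
    every homology sits in an undersized block do not appear.
    """
    H = nx.Graph()
    for table in tables:
        for gene_a, gene_b in table.pairs(min_block_size):
            u: GeneKey = (table.genome_a, gene_a)
            v: GeneKey = (table.genome_b, gene_b)
            if u == v or u[0] == v[0]:
                continue  # tables are cross-genome; ignore degenerate rows
            H.add_edge(u, v)
    return H


def transitive_closure(P: nx.Graph) -> nx.Graph:
    """Each connected component becomes a clique; idempotent."""
    Q = nx.Graph()
    Q.add_nodes_from(P.nodes)
    for comp in nx.connected_components(P):
        comp = sorted(comp)
        for i, u in enumerate(comp):
            for v in comp[i + 1 :]:
                Q.add_edge(u, v)
    return Q


def prefilter_components(H: nx.Graph, tree: PhyloTree) -> nx.Graph:
    """Drop two-gene components whose genomes are phylogenetically remote.

    A component holding just two genes from genomes separated by three or
    more ancestral nodes cannot contribute an ancestral ortholog, so it is
    removed before resolution.
    """
    keep = nx.Graph()
    keep.add_nodes_from(H.nodes)
    keep.add_edges_from(H.edges)
    for comp in list(nx.connected_components(H)):
        if len(comp) != 2:
            continue
        (ga, _), (gb, _) = sorted(comp)
        for g in (ga, gb):
            if not tree.has_leaf(g):
                raise ValueError(f"genome {g!r} is not a leaf of the tree")
        if tree.internal_nodes_between(ga, gb) >= 3:
            keep.remove_nodes_from(comp)
    return keep


def decompose_tangle(G: nx.Graph, size_threshold: int = TANGLE_THRESHOLD) -> list:
    """Split an oversized component into tractable pieces.

    Repeatedly extracts the maximum-degree vertex together with its
    immediate homologs (its closed neighbourhood) as one piece, recursing
    on what remains.  A piece that is itself a closed neighbourhood is
    returned whole even when larger than the threshold.
    """
    if G.number_of_nodes() <= size_threshold:
        return [G]
    hub = max(sorted(G.nodes), key=lambda v: G.degree(v))
    piece = {hub} | set(G.neighbors(hub))
    out = [G.subgraph(piece).copy()]
    rest = G.subgraph(set(G.nodes) - piece)
    for comp in nx.connected_components(rest):
        out.extend(decompose_tangle(rest.subgraph(comp).copy(), size_threshold))
    return out


# ---------------------------------------------------------------------------
# greedy edge deletion
# ---------------------------------------------------------------------------


def _allowance(genome: str, wgd_genomes: set) -> int:
    return 2 if genome in wgd_genomes else 1


def _comp_closure_stats(comp: Sequence[GeneKey], wgd_genomes: set) -> tuple[int, int, bool]:
    """(F+ contribution, objective contribution, compliant) of one closure clique.

    In the transitive closure a component is a clique, so every vertex's
    star is the whole component: nu(v) = |comp| and c(v) is the genome
    count with the WGD allowance applied.  The objective contribution
    |comp| * c is the clique reading of "total edges in the closure".
    """
    counts: dict[str, int] = {}
    for genome, _ in comp:
        counts[genome] = counts.get(genome, 0) + 1
    c = sum(min(n, _allowance(g, wgd_genomes)) for g, n in counts.items())
    nu = len(comp)
    compliant = all(
        n <= _allowance(g, wgd_genomes) for g, n in counts.items()
    )
    return nu * (nu - c), nu * c, compliant


def _edge_key(e: tuple[GeneKey, GeneKey]) -> tuple:
    return tuple(sorted(e))


def _star_counts(graph: nx.Graph) -> dict:
    """For each vertex: genome multiplicities in its star (v + neighbours)."""
    out = {}
    for v in graph.nodes:
        counts: dict[str, int] = {v[0]: 1}
        for u in graph.neighbors(v):
            counts[u[0]] = counts.get(u[0], 0) + 1
        out[v] = counts
    return out


def resolve_component(
    G: nx.Graph, wgd_genomes: Iterable[str] = ()
) -> list[frozenset]:
    """Greedy edge deletion until every component is paralogy-free.

    ``G`` is one connected component (or tangle piece) of the homology
    graph.  While some component of the closure still holds more genes of
    one genome than allowed, the reported edge whose removal keeps
    F = sum_v c(v) (computed on the stars of the remaining graph) largest
    is deleted; ties go to the candidate minimizing the residual paralogy
    F+ = sum_v (nu(v) - c(v)) on the closure, then to the candidate
    maximizing the closure objective itself, then to the smallest edge
    key.  For paralogy-free cliques F equals the sum of squared component
    sizes, so the greedy favours splitting off one small piece over
    halving a component.  Returns the vertex sets of the final components
    (a partition of the input vertices, singletons included).
    """
    wgd = set(wgd_genomes)
    work = G.copy()

    while True:
        comps = [sorted(c) for c in nx.connected_components(work)]
        closure = [_comp_closure_stats(c, wgd) for c in comps]
        if all(ok for _fp, _obj, ok in closure):
            break
        Fp_cur = sum(fp for fp, _obj, _ok in closure)
        obj_cur = sum(obj for _fp, obj, _ok in closure)
        node_comp = {v: i for i, c in enumerate(comps) for v in c}

        stars = _star_counts(work)
        c_of = {
            v: sum(min(n, _allowance(g, wgd)) for g, n in counts.items())
            for v, counts in stars.items()
        }
        F_cur = sum(c_of.values())

        def star_loss(u: GeneKey, v: GeneKey) -> int:
            # c(u) after removing v from u's star drops by one exactly when
            # v's genome is not over-represented beyond its allowance
            n = stars[u][v[0]]
            return 1 if n <= _allowance(v[0], wgd) else 0

        bridges = {_edge_key(e) for e in nx.bridges(work)}
        best = None
        for e in sorted(_edge_key(e) for e in work.edges):
            u, v = e
            F_new = F_cur - star_loss(u, v) - star_loss(v, u)
            if e in bridges:
                i = node_comp[u]
                side = sorted(_bfs_side(work, u, v))
                other = [x for x in comps[i] if x not in set(side)]
                fp_a, obj_a, _ = _comp_closure_stats(side, wgd)
                fp_b, obj_b, _ = _comp_closure_stats(other, wgd)
                Fp_new = Fp_cur - closure[i][0] + fp_a + fp_b
                obj_new = obj_cur - closure[i][1] + obj_a + obj_b
            else:
                Fp_new = Fp_cur
                obj_new = obj_cur
            cand = (-F_new, Fp_new, -obj_new, e)
            if best is None or cand < best:
                best = cand
        assert best is not None, "paralogous component with no deletable edge"
        work.remove_edge(*best[3])

    return [frozenset(c) for c in nx.connected_components(work)]


def _bfs_side(graph: nx.Graph, u: GeneKey, v: GeneKey) -> set:
    """Vertices reachable from ``u`` when bridge (u, v) is removed."""
    seen = {u}
    stack = [u]
    while stack:
        x = stack.pop()
        for y in graph.neighbors(x):
            if (x, y) in ((u, v), (v, u)):
                continue
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def omg(
    tables: Iterable[PairwiseHomologyTable],
    tree: PhyloTree,
    min_block_size: int = 1,
    wgd_genomes: Iterable[str] = (),
    tangle_threshold: int = TANGLE_THRESHOLD,
) -> list[OrthologySet]:
    """Decompose pooled pairwise homologies into paralogy-free orthology sets.

    Pipeline: build graph -> prefilter remote two-gene components -> split
    tangles -> greedy resolution per component.  Singleton leftovers carry
    no gene-order information and are discarded; the surviving sets are
    numbered deterministically.
    """
    wgd = set(wgd_genomes)
    H = build_homology_graph(tables, min_block_size)
    H = prefilter_components(H, tree)
    raw_sets: list[frozenset] = []
    for comp in nx.connected_components(H):
        sub = H.subgraph(comp).copy()
        for piece in decompose_tangle(sub, tangle_threshold):
            raw_sets.extend(resolve_component(piece, wgd))
    raw_sets = [s for s in raw_sets if len(s) >= 2]
    raw_sets.sort(key=lambda s: sorted(s))
    out = []
    for i, s in enumerate(raw_sets, start=1):
        out.append(OrthologySet(id=f"OS{i:06d}", genes=s))
        _check_paralogy_free(out[-1], wgd)
    return out


def _check_paralogy_free(oset: OrthologySet, wgd: set) -> None:
    counts: dict[str, int] = {}
    for genome, _ in oset.genes:
        counts[genome] = counts.get(genome, 0) + 1
    for genome, n in counts.items():
        if n > _allowance(genome, wgd):
            raise AssertionError(
                f"orthology set {oset.id} keeps {n} genes of {genome!r}"
            )


def orthoset_assignment(
    orthosets: Iterable[OrthologySet],
) -> dict[str, dict[str, Hashable]]:
    """Per-genome mapping gene_id -> orthoset_id."""
    out: dict[str, dict[str, Hashable]] = {}
    for oset in orthosets:
        for genome, gene in oset.genes:
            out.setdefault(genome, {})[gene] = oset.id
    return out
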