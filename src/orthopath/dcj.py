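"""Breakpoint graph and DCJ genomic distance.

Each gene ``g`` contributes a tail vertex ``g_t`` and a head vertex
``g_h``.  Consecutive genes on a chromosome define adjacencies (unordered
vertex pairs); chromosome ends are capped with ``T1`` (genome 1) or ``T2``
(genome 2) vertices.  Blue edges are the adjacencies of genome 1, red edges
those of genome 2.  After capping, paths ending in two T1 caps are closed
by a red edge, paths ending in two T2 caps by a blue edge, and T1-T2 paths
collapse their caps into a single T; the graph then decomposes uniquely
into kappa alternating cycles and the genomic distance is

    d(G1, G2) = n' - kappa

with n' the number of blue edges (including T2-T2 closures).

The fragment correction removes the fusions/fissions that merely equalize
chromosome (or assembly-fragment) counts: each T1-T1 or T2-T2 closure
corresponds to one such artifactual operation, so the surplus of one kind
over the other is subtracted from the raw distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

from .genomes import Genome

__all__ = [
    "BreakpointGraph",
    "ContentMismatchError",
    "adjacencies",
    "build_breakpoint_graph",
    "dcj_distance",
    "dcj_distance_orders",
    "fragment_corrected_distance",
]

SignedOrder = Sequence[Sequence[tuple[Hashable, int]]]


class ContentMismatchError(ValueError):
    """The two genomes do not share the same gene-label set."""


def _as_orders(g, by: str) -> list:
    if isinstance(g, Genome):
        return g.signed_orders(by)
    return [tuple(chrom) for chrom in g]


def _vertex_walk(chrom) -> list:
    """Extremities of a chromosome in left-to-right order."""
    verts = []
    for label, sign in chrom:
        if sign > 0:
            verts.append((label, "t"))
            verts.append((label, "h"))
        else:
            verts.append((label, "h"))
            verts.append((label, "t"))
    return verts


def _edge_map(orders, capcolor: str) -> dict:
    """Perfect matching vertex -> partner for one genome, with caps."""
    partner: dict = {}
    capid = 0
    for chrom in orders:
        verts = _vertex_walk(chrom)
        for cap_vertex, end_vertex in (
            ((capcolor, capid), verts[0]),
            ((capcolor, capid + 1), verts[-1]),
        ):
            partner[cap_vertex] = end_vertex
            partner[end_vertex] = cap_vertex
        capid += 2
        for i in range(1, len(verts) - 1, 2):
            partner[verts[i]] = verts[i + 1]
            partner[verts[i + 1]] = verts[i]
    return partner


def _check_content(o1, o2) -> None:
    def labels(orders):
        out = []
        for chrom in orders:
            out.extend(l for l, _s in chrom)
        return out

    l1, l2 = labels(o1), labels(o2)
    if len(set(l1)) != len(l1) or len(set(l2)) != len(l2):
        dupes = sorted(
            {x for lab in (l1, l2) for x in lab if lab.count(x) > 1}, key=repr
        )
        raise ContentMismatchError(f"duplicated gene labels: {dupes}")
    if set(l1) != set(l2):
        diff = sorted(set(l1) ^ set(l2), key=repr)
        raise ContentMismatchError(f"gene content differs on labels: {diff}")


@dataclass
class BreakpointGraph:
    """Capped bicoloured graph of two genomes and its cycle decomposition."""

    blue_edges: list
    red_edges: list
    n_prime: int
    kappa: int
    t1t1_closures: int
    t2t2_closures: int

    @property
    def distance(self) -> int:
        return self.n_prime - self.kappa


def _decompose(o1, o2) -> tuple[int, int, int, int]:
    """(n_prime, kappa, t1t1, t2t2) for two equal-content signed orders."""
    blue = _edge_map(o1, "T1")
    red = _edge_map(o2, "T2")
    n_blue = sum(len(chrom) + 1 for chrom in o1)

    visited: set = set()
    kappa = t1t1 = t2t2 = 0
    caps = [v for v in blue if v[0] == "T1"] + [v for v in red if v[0] == "T2"]
    for cap in caps:
        if cap in visited:
            continue
        visited.add(cap)
        start_color = cap[0]
        cur = blue[cap] if start_color == "T1" else red[cap]
        use_red = start_color == "T1"  # next edge colour to follow
        while cur[0] not in ("T1", "T2"):
            visited.add(cur)
            cur = red[cur] if use_red else blue[cur]
            use_red = not use_red
        visited.add(cur)
        kappa += 1
        if start_color == cur[0] == "T1":
            t1t1 += 1
        elif start_color == cur[0] == "T2":
            t2t2 += 1
    for v in blue:
        if v in visited or v[0] == "T1":
            continue
        # proper alternating cycle
        cur = v
        use_red = False
        while cur not in visited:
            visited.add(cur)
            cur = red[cur] if use_red else blue[cur]
            use_red = not use_red
        kappa += 1
    # a T2-T2 path is closed by an extra blue edge, which counts in n'
    return n_blue + t2t2, kappa, t1t1, t2t2


def adjacencies(g, by: str = "gene") -> set:
    """Adjacencies of a genome as unordered extremity pairs, with caps.

    Telomeric extremities are paired with unique ``('CAP', i)`` vertices.
    """
    orders = _as_orders(g, by)
    out: set = set()
    capid = 0
    for chrom in orders:
        verts = _vertex_walk(chrom)
        out.add(frozenset({("CAP", capid), verts[0]}))
        out.add(frozenset({verts[-1], ("CAP", capid + 1)}))
        capid += 2
        for i in range(1, len(verts) - 1, 2):
            out.add(frozenset({verts[i], verts[i + 1]}))
    return out


def build_breakpoint_graph(g1, g2, by: str = "gene") -> BreakpointGraph:
    o1, o2 = _as_orders(g1, by), _as_orders(g2, by)
    _check_content(o1, o2)
    n_prime, kappa, t1t1, t2t2 = _decompose(o1, o2)
    blue = _edge_map(o1, "T1")
    red = _edge_map(o2, "T2")
    blue_edges = sorted(
        {frozenset((a, b)) for a, b in blue.items()},
        key=lambda e: sorted(map(repr, e)),
    )
    red_edges = sorted(
        {frozenset((a, b)) for a, b in red.items()},
        key=lambda e: sorted(map(repr, e)),
    )
    return BreakpointGraph(blue_edges, red_edges, n_prime, kappa, t1t1, t2t2)


def dcj_distance_orders(o1: SignedOrder, o2: SignedOrder) -> int:
    """Fast path: DCJ distance between two equal-content signed orders."""
    if not o1 and not o2:
        return 0
    n_prime, kappa, _, _ = _decompose(o1, o2)
    return n_prime - kappa


def dcj_distance(g1, g2, by: str = "gene") -> int:
    """Minimum number of DCJ operations transforming ``g1`` into ``g2``."""
    o1, o2 = _as_orders(g1, by), _as_orders(g2, by)
    _check_content(o1, o2)
    return dcj_distance_orders(o1, o2)


def fragment_corrected_distance(g1, g2, by: str = "gene") -> int:
    """DCJ distance minus artifactual fusions/fissions due to fragmentation.

    Chromosome/fragment-count differences force ``|chi1 - chi2|`` fusions
    or fissions into any scenario; these appear in the capped breakpoint
    graph as same-genome cap closures (T1-T1 or T2-T2).  The surplus of one
    closure kind over the other is removed from the score, clamped so the
    corrected distance is never negative.
    """
    o1, o2 = _as_orders(g1, by), _as_orders(g2, by)
    _check_content(o1, o2)
    if not o1 and not o2:
        return 0
    n_prime, kappa, t1t1, t2t2 = _decompose(o1, o2)
    d = n_prime - kappa
    return max(0, d - abs(t1t1 - t2t2))
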