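"""Greedy ancestral gene-order reconstruction (pathgroups heuristic).

An ancestral genome is built as a set of red adjacency edges shared by the
breakpoint graphs of all branches incident to that ancestor.  A *path* is
any connected part of a cycle in one of those partial breakpoint graphs; a
*pathgroup* bundles the paths starting at one ancestral extremity, one per
incident branch (two for the branch to a WGD descendant, none for a branch
whose genome lacks the gene).  A *fragment* is a maximal run of ancestral
genes already connected by red edges; fragments partition the ancestral
gene set at all times and are kept linear — a red edge joining the two
ends of one fragment would create a circular chromosome and is never
allowed.

At each step the solver adds the red edge that closes the most alternating
cycles immediately, breaking ties by the best number of cycles that any
pathgroup affected by the choice could close next (one-step look-ahead),
then by a deterministic vertex key.  With per-priority buckets this runs
in near-linear time in the number of genes.

Genomes with unequal gene content are handled by restricting each branch's
breakpoint graph to the genes shared by the ancestor and that neighbour:
runs of genes absent from the ancestor are skipped when the neighbour's
adjacencies are formed, which is exactly the "hidden cycle" extension
through absent genes, applied once up front; red edges whose gene is
missing from a neighbour are simply left out of that branch's graph.

A WGD descendant T is attached through a doubled ancestor A built from the
genes present twice in T.  Each red edge of A is realized twice in the
T-branch, and the pairing of the two copies is chosen to maximize cycles.
After reconstruction, runs of single-copy genes from T are re-inserted
next to both copies of a flanking duplicated gene, and a crude
fractionation correction of s/3 per single-copy run of length s > 3 is
subtracted from the A-R branch length.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .dcj import dcj_distance_orders, _decompose, _edge_map
from .genomes import Chromosome, Genome
from .gene_content import ContentAssignment, assign_content
from .homology import PairwiseHomologyTable
from .omg import OrthologySet
from .trees import PhyloTree

__all__ = [
    "PathGroup",
    "construct_ancestor",
    "median",
    "small_phylogeny",
    "SmallPhylogenyResult",
    "hidden_cycle_search",
    "doubled_distance",
    "single_copy_runs",
    "reinsert_single_copy_runs",
    "fractionation_correction",
    "block_integrity",
    "restricted_distance",
]

_REMOVED = object()


def _vkey(v) -> str:
    return repr(v)


class _Overlay:
    """Copy-on-write view over a branch's endpoint map."""

    __slots__ = ("base", "data")

    def __init__(self, base: dict):
        self.base = base
        self.data: dict = {}

    def get(self, k):
        if k in self.data:
            v = self.data[k]
            return None if v is _REMOVED else v
        return self.base.get(k)

    def set(self, k, v):
        self.data[k] = v

    def remove(self, k):
        self.data[k] = _REMOVED


def _orders_to_vertex_chain(chrom) -> list:
    out = []
    for label, sign in chrom:
        if sign > 0:
            out.append((label, "t"))
            out.append((label, "h"))
        else:
            out.append((label, "h"))
            out.append((label, "t"))
    return out


class _SimpleBranch:
    """Breakpoint graph vs. one neighbour genome (one path per pathgroup)."""

    def __init__(self, branch_id: str, orders, content: set):
        self.branch_id = branch_id
        self.cycles = 0
        self.end: dict = {}
        self.vertices: set = set()
        capid = 0
        for chrom in orders:
            row = [(l, s) for l, s in chrom if l in content]
            if not row:
                continue
            verts = _orders_to_vertex_chain(row)
            self.vertices.update(verts)
            caps = (("cap", branch_id, capid), ("cap", branch_id, capid + 1))
            capid += 2
            self.end[caps[0]] = verts[0]
            self.end[verts[0]] = caps[0]
            for i in range(1, len(verts) - 1, 2):
                self.end[verts[i]] = verts[i + 1]
                self.end[verts[i + 1]] = verts[i]
            self.end[verts[-1]] = caps[1]
            self.end[caps[1]] = verts[-1]

    def n_paths(self, x) -> int:
        return 1 if x in self.vertices else 0

    def candidate_partners(self, x, ov: _Overlay | None = None) -> list:
        if x not in self.vertices:
            return []
        e = ov.get(x) if ov else self.end.get(x)
        if e is None or e[0] == "cap":
            return []
        return [e]

    def gain(self, x, y, ov: _Overlay | None = None) -> int:
        """Change in (cycles - ancestor-telomere-pair closures) from {x, y}.

        Closing a cycle gains one; joining two paths that both already end
        at a leaf cap forfeits one capped-path cycle; other joins are
        neutral.  This is the telomere-aware bookkeeping of the distance
        formula: a path capped on the leaf side always closes into a
        cycle, while a path capped on the ancestor side at both ends is
        cancelled by its closure edge.
        """
        if x not in self.vertices or y not in self.vertices:
            return 0
        ex = ov.get(x) if ov else self.end.get(x)
        if ex == y:
            return 1
        ey = ov.get(y) if ov else self.end.get(y)
        if ex is not None and ey is not None and ex[0] == "cap" and ey[0] == "cap":
            return -1
        return 0

    def apply(self, x, y) -> set:
        """Add red edge {x, y}; returns ancestor vertices whose paths changed."""
        if x not in self.vertices or y not in self.vertices:
            return set()
        a = self.end.pop(x)
        b = self.end.pop(y)
        if a == y:  # two ends of the same path: a cycle closes
            self.cycles += 1
            return set()
        self.end[a] = b
        self.end[b] = a
        return {v for v in (a, b) if v[0] != "cap"}

    def overlay_apply(self, x, y) -> tuple[_Overlay | None, set]:
        if x not in self.vertices or y not in self.vertices:
            return None, set()
        a = self.end.get(x)
        b = self.end.get(y)
        if a is None or b is None:  # consumed here via another pathgroup
            return None, set()
        ov = _Overlay(self.end)
        ov.remove(x)
        ov.remove(y)
        if a == y:
            return ov, set()
        ov.set(a, b)
        ov.set(b, a)
        return ov, {v for v in (a, b) if v[0] != "cap"}


class _DoubleBranch:
    """Breakpoint graph vs. a WGD descendant (two paths per pathgroup).

    Branch vertices live in copy space: ``(ancestor_vertex, copy)``.  Each
    red ancestor edge {x, y} is realized as two edges pairing the copies;
    the pairing with more immediate cycles is chosen.
    """

    PAIRINGS = ((1, 2), (2, 1))

    def __init__(self, branch_id: str, copy_orders, content: set):
        # copy_orders: neighbour chromosomes over ((label, copy), sign)
        self.branch_id = branch_id
        self.cycles = 0
        self.end: dict = {}
        self.keys: set = set(content)
        capid = 0
        for chrom in copy_orders:
            row = [(lc, s) for lc, s in chrom if lc[0] in content]
            if not row:
                continue
            verts = []
            for (label, copy), sign in row:
                a, b = ("t", "h") if sign > 0 else ("h", "t")
                verts.append(((label, a), copy))
                verts.append(((label, b), copy))
            caps = (("cap", branch_id, capid), ("cap", branch_id, capid + 1))
            capid += 2
            self.end[caps[0]] = verts[0]
            self.end[verts[0]] = caps[0]
            for i in range(1, len(verts) - 1, 2):
                self.end[verts[i]] = verts[i + 1]
                self.end[verts[i + 1]] = verts[i]
            self.end[verts[-1]] = caps[1]
            self.end[caps[1]] = verts[-1]
        self.n_blue = sum(
            1 for chrom in copy_orders for lc, _ in chrom if lc[0] in content
        ) + capid // 2

    def n_paths(self, x) -> int:
        return 2 if x[0] in self.keys else 0

    def _has(self, v) -> bool:
        return v[0] in self.keys

    def candidate_partners(self, x, ov: _Overlay | None = None) -> list:
        if not self._has(x):
            return []
        out = []
        for copy in (1, 2):
            e = ov.get((x, copy)) if ov else self.end.get((x, copy))
            if e is not None and e[0] != "cap":
                out.append(e[0])
        return out

    def _pair_gain(self, x, y, endget):
        """Try both copy pairings; returns (gain, pairing).

        Gains use the same telomere-aware bookkeeping as simple branches:
        +1 per closed cycle, -1 per join of two leaf-capped paths.
        """
        best = (None, None)
        for pairing in self.PAIRINGS:
            snapshot: dict = {}

            def get(k, snapshot=snapshot):
                return snapshot[k] if k in snapshot else endget(k)

            gain = 0
            ok = True
            for ci, cj in zip((1, 2), pairing):
                u, v = (x, ci), (y, cj)
                a, b = get(u), get(v)
                if a is None or b is None:
                    ok = False
                    break
                snapshot[u] = None
                snapshot[v] = None
                if a == v:
                    gain += 1
                else:
                    if a[0] == "cap" and b[0] == "cap":
                        gain -= 1
                    snapshot[a] = b
                    snapshot[b] = a
            if ok and (best[0] is None or gain > best[0]):
                best = (gain, pairing)
        return best

    def gain(self, x, y, ov: _Overlay | None = None) -> int:
        if not (self._has(x) and self._has(y)):
            return 0
        endget = (lambda k: ov.get(k)) if ov else (lambda k: self.end.get(k))
        g, _ = self._pair_gain(x, y, endget)
        return g if g is not None else 0

    def _commit(self, x, y, pairing, endmap_get, endmap_set, endmap_del) -> tuple[int, set]:
        cycles = 0
        affected: set = set()
        for ci, cj in zip((1, 2), pairing):
            u, v = (x, ci), (y, cj)
            a, b = endmap_get(u), endmap_get(v)
            endmap_del(u)
            endmap_del(v)
            if a == v:
                cycles += 1
            else:
                endmap_set(a, b)
                endmap_set(b, a)
                for w in (a, b):
                    if w[0] != "cap":
                        affected.add(w[0])
        return cycles, affected

    def apply(self, x, y) -> set:
        if not (self._has(x) and self._has(y)):
            return set()
        _, pairing = self._pair_gain(x, y, lambda k: self.end.get(k))
        if pairing is None:
            return set()
        cycles, affected = self._commit(
            x,
            y,
            pairing,
            lambda k: self.end.get(k),
            lambda k, v: self.end.__setitem__(k, v),
            lambda k: self.end.pop(k, None),
        )
        self.cycles += cycles
        return affected

    def overlay_apply(self, x, y) -> tuple[_Overlay | None, set]:
        if not (self._has(x) and self._has(y)):
            return None, set()
        ov = _Overlay(self.end)
        _, pairing = self._pair_gain(x, y, lambda k: self.end.get(k))
        if pairing is None:
            return None, set()
        _, affected = self._commit(
            x, y, pairing, ov.get, ov.set, ov.remove
        )
        return ov, affected


@dataclass
class PathGroup:
    """Inspection view: paths (branch id, current far endpoint) at a vertex."""

    start: tuple
    paths: list
    priority: tuple  # (immediate_cycles, lookahead_cycles)
    best_partner: tuple | None


class _AncestorSolver:
    """Builds one ancestral genome from its incident branches."""

    def __init__(self, content: Sequence[Hashable], branches: list):
        self.content = sorted(content, key=_vkey)
        if not self.content:
            raise ValueError("ancestor gene content is empty")
        self.branches = branches
        self.frag_partner: dict = {}
        for k in self.content:
            self.frag_partner[(k, "t")] = (k, "h")
            self.frag_partner[(k, "h")] = (k, "t")
        self.used: set = set()
        self.red_edges: list = []

    # -- priorities -----------------------------------------------------

    def _candidates(self, x) -> list:
        ys: set = set()
        for br in self.branches:
            ys.update(br.candidate_partners(x))
        blocked = self.frag_partner.get(x)
        return sorted(
            (y for y in ys if y != x and y != blocked and y not in self.used),
            key=_vkey,
        )

    def _immediate(self, x, y) -> int:
        return sum(br.gain(x, y) for br in self.branches)

    def _lookahead(self, x, y) -> int:
        overlays = []
        affected: set = set()
        for br in self.branches:
            ov, aff = br.overlay_apply(x, y)
            overlays.append(ov)
            affected |= aff
        # fragment ends after the hypothetical join
        p = self.frag_partner.get(x)
        q = self.frag_partner.get(y)
        best = 0
        for w in sorted(affected, key=_vkey):
            if w in (x, y) or w in self.used:
                continue
            blocked = q if w == p else (p if w == q else self.frag_partner.get(w))
            zs: set = set()
            for br, ov in zip(self.branches, overlays):
                zs.update(br.candidate_partners(w, ov))
            for z in zs:
                if z in (w, x, y, blocked) or z in self.used:
                    continue
                imm = sum(
                    br.gain(w, z, ov) for br, ov in zip(self.branches, overlays)
                )
                if imm > best:
                    best = imm
        return best

    def best_move(self, x):
        """(immediate gain, lookahead gain, partner) of the best red edge.

        Moves with a negative total gain are never proposed: leaving both
        extremities as ancestral telomeres is then at least as good.
        """
        best = None
        for y in self._candidates(x):
            imm = self._immediate(x, y)
            if imm < 0:
                continue
            la = self._lookahead(x, y)
            cand = (-imm, -la, _vkey(y))
            if best is None or cand < best[0]:
                best = (cand, (imm, la, y))
        return None if best is None else best[1]

    def pathgroup(self, x) -> PathGroup:
        paths = []
        for br in self.branches:
            if isinstance(br, _DoubleBranch):
                for copy in (1, 2):
                    e = br.end.get((x, copy))
                    if e is not None:
                        paths.append((br.branch_id, e))
            else:
                e = br.end.get(x)
                if e is not None:
                    paths.append((br.branch_id, e))
        mv = self.best_move(x)
        if mv is None:
            return PathGroup(x, paths, (0, 0), None)
        return PathGroup(x, paths, (mv[0], mv[1]), mv[2])

    # -- main loop ------------------------------------------------------

    def _apply(self, x, y) -> set:
        affected: set = set()
        for br in self.branches:
            affected |= br.apply(x, y)
        self.used.add(x)
        self.used.add(y)
        p = self.frag_partner.pop(x)
        q = self.frag_partner.pop(y)
        self.frag_partner[p] = q
        self.frag_partner[q] = p
        self.red_edges.append((x, y))
        # a vertex consumed here may still be a live endpoint in branches
        # that skipped the edge (absent gene); never revisit used vertices
        return {v for v in affected | {p, q} if v not in self.used}

    def solve(self) -> None:
        heap: list = []

        def push(x):
            if x in self.used:
                return
            mv = self.best_move(x)
            if mv is not None:
                imm, la, y = mv
                heapq.heappush(heap, (-imm, -la, _vkey(x), _vkey(y), x, y))

        for k in self.content:
            push((k, "t"))
            push((k, "h"))
        while heap:
            negimm, negla, _kx, _ky, x, y = heapq.heappop(heap)
            if x in self.used:
                continue
            mv = self.best_move(x)
            if mv is None:
                continue
            if (-mv[0], -mv[1], _vkey(mv[2])) != (negimm, negla, _ky):
                push(x)
                continue
            for w in self._apply(x, mv[2]):
                push(w)

    # -- result ---------------------------------------------------------

    def ancestor_orders(self) -> list:
        red = {}
        for x, y in self.red_edges:
            red[x] = y
            red[y] = x
        seen: set = set()
        chroms = []
        telomeres = [
            (k, e)
            for k in self.content
            for e in ("t", "h")
            if (k, e) not in self.used
        ]
        for t in telomeres:
            if t in seen:
                continue
            row = []
            v = t
            while True:
                seen.add(v)
                key, endp = v
                row.append((key, 1 if endp == "t" else -1))
                other = (key, "h" if endp == "t" else "t")
                seen.add(other)
                if other not in red:
                    break
                v = red[other]
            chroms.append(tuple(row))
        # deterministic chromosome order
        chroms.sort(key=lambda c: _vkey(c))
        return chroms

    def total_cycles(self) -> int:
        return sum(br.cycles for br in self.branches)


# ---------------------------------------------------------------------------
# public construction helpers
# ---------------------------------------------------------------------------


def _genome_orders(g, by: str | None = None):
    if isinstance(g, Genome):
        if by is None:
            by = "orthoset" if any(
                x.orthoset_id is not None for x in g.genes.values()
            ) else "gene"
        return g.signed_orders(by)
    return [tuple(chrom) for chrom in g]


def _orders_keys(orders) -> set:
    return {l for chrom in orders for l, _s in chrom}


def _copy_orders(orders):
    """Orders labelled (key, copy) from a WGD descendant's orthoset orders."""
    out = []
    for chrom in orders:
        row = []
        for label, sign in chrom:
            if isinstance(label, tuple) and len(label) == 2 and label[1] in (1, 2):
                row.append((label, sign))
            else:
                row.append(((label, 1), sign))
        out.append(tuple(row))
    return out


def _duplicated_keys(copy_orders) -> set:
    counts: dict = {}
    for chrom in copy_orders:
        for (key, _c), _s in chrom:
            counts[key] = counts.get(key, 0) + 1
    return {k for k, n in counts.items() if n == 2}


def construct_ancestor(
    neighbor_specs: Sequence[tuple[str, str, object]],
    content: Iterable[Hashable],
    name: str = "M",
) -> tuple[Genome, _AncestorSolver]:
    """Build an ancestor from branch specs ``(kind, branch_id, orders)``.

    ``kind`` is ``'simple'`` (orders over gene keys) or ``'double'`` (orders
    over ``(key, copy)`` from a WGD descendant).  The ancestor has exactly
    the genes of ``content``, arranged on linear fragments.
    """
    content = set(content)
    if not content:
        raise ValueError("ancestor gene content is empty")
    branches = []
    for kind, branch_id, orders in neighbor_specs:
        if kind == "simple":
            branches.append(_SimpleBranch(branch_id, orders, content))
        elif kind == "double":
            branches.append(_DoubleBranch(branch_id, orders, content))
        else:
            raise ValueError(f"unknown branch kind {kind!r}")
    solver = _AncestorSolver(content, branches)
    solver.solve()
    chroms = [
        Chromosome(tuple((str(k), s) for k, s in chrom), is_fragment=True)
        for chrom in solver.ancestor_orders()
    ]
    genome = Genome(name, chroms)
    genome = genome.with_orthosets({str(k): k for k in content})
    return genome, solver


def restricted_distance(g1, g2, by1: str | None = None, by2: str | None = None) -> int:
    """DCJ distance between the induced sub-genomes on shared gene labels."""
    o1 = _genome_orders(g1, by1)
    o2 = _genome_orders(g2, by2)
    common = _orders_keys(o1) & _orders_keys(o2)
    r1 = [r for r in ([(l, s) for l, s in c if l in common] for c in o1) if r]
    r2 = [r for r in ([(l, s) for l, s in c if l in common] for c in o2) if r]
    return dcj_distance_orders(r1, r2)


def median(
    g1: Genome,
    g2: Genome,
    g3: Genome,
    content: Iterable[Hashable] | None = None,
    by: str | None = None,
    name: str = "M",
) -> tuple[Genome, tuple[int, int, int]]:
    """Approximate rearrangement median of three genomes.

    ``content`` defaults to the genes present in at least two of the three
    genomes (the majority rule used for ancestral gene content).  Returns
    the median genome on linear fragments and its three branch distances,
    each computed on the gene content shared with that input genome.
    """
    orders = [_genome_orders(g, by) for g in (g1, g2, g3)]
    keysets = [_orders_keys(o) for o in orders]
    if content is None:
        content = {
            k
            for ks in keysets
            for k in ks
            if sum(k in other for other in keysets) >= 2
        }
    content = set(content)
    if not content:
        raise ValueError("median gene content is empty")
    union = keysets[0] | keysets[1] | keysets[2]
    if not content <= union:
        raise ValueError("content contains genes absent from all three genomes")
    specs = [
        ("simple", f"b{i}", o) for i, o in enumerate(orders)
    ]
    M, _solver = construct_ancestor(specs, content, name=name)
    dists = tuple(
        restricted_distance(M, o, by1="gene", by2=None) for o in orders
    )
    return M, dists


# ---------------------------------------------------------------------------
# hidden cycles (unequal gene content)
# ---------------------------------------------------------------------------


def hidden_cycle_search(path, absent_genes, partner_genome, by: str | None = None) -> int:
    """Extra cycles revealed by extending a path through absent genes.

    ``path`` is the pair of current endpoint vertices ``((gene, end), ...)``
    of a path in the partner genome's breakpoint graph.  Endpoints lying on
    genes absent from the ancestor are extended vertex by vertex along the
    partner's adjacencies until a retained gene's extremity or a chromosome
    cap is met.  One hidden cycle is reported when both (extended)
    endpoints land on retained extremities that a single red edge could
    join, or when both land on caps (a telomere-to-telomere closure);
    otherwise the path stays open and counts nothing.
    """
    absent = set(absent_genes)
    orders = _genome_orders(partner_genome, by)
    blue = _edge_map(orders, "T1")

    def extend(v):
        moved = False
        while v[0] != "T1" and v[0] in absent:
            other = (v[0], "h" if v[1] == "t" else "t")
            v = blue[other]
            moved = True
        return v, moved

    a, b = path
    a2, ma = extend(a)
    b2, mb = extend(b)
    if not (ma or mb):
        return 0
    a_cap = a2[0] == "T1"
    b_cap = b2[0] == "T1"
    if a_cap and b_cap:
        return 1
    if not a_cap and not b_cap and a2 != b2:
        return 1
    return 0


# ---------------------------------------------------------------------------
# WGD: halving distance, single-copy runs, fractionation
# ---------------------------------------------------------------------------


def doubled_distance(T: Genome, half: Genome) -> int:
    """DCJ distance between a WGD descendant and a doubled half-genome.

    ``half`` holds one copy of each duplicated gene; it is compared to
    ``T`` as the perfectly doubled genome ``half + half``.  The copy
    pairing of each adjacency is chosen greedily to maximize cycles, so
    the value is an upper bound on the exact double-distance (tight on all
    small cases we can enumerate).
    """
    copy_orders = _copy_orders(_genome_orders(T, None))
    half_orders = _genome_orders(half, None)
    dup = _duplicated_keys(copy_orders)
    common = dup & _orders_keys(half_orders)
    branch = _DoubleBranch("w", copy_orders, common)
    half_rows = [
        r
        for r in ([(l, s) for l, s in c if l in common] for c in half_orders)
        if r
    ]
    for chrom in half_rows:
        verts = _orders_to_vertex_chain(chrom)
        for i in range(1, len(verts) - 1, 2):
            branch.apply(verts[i], verts[i + 1])
    kappa = branch.cycles
    # close remaining paths by the capping rules: ends are either T caps
    # or extremities of the doubled ancestor (its telomeres)
    seen: set = set()
    n_prime = branch.n_blue
    for v, w in branch.end.items():
        if v in seen or w in seen:
            continue
        seen.add(v)
        seen.add(w)
        kappa += 1
        v_cap = v[0] == "cap"
        w_cap = w[0] == "cap"
        if not v_cap and not w_cap:
            n_prime += 1  # ancestor-telomere pair closed by a blue edge
    return n_prime - kappa


def single_copy_runs(T: Genome) -> list:
    """Maximal runs of single-copy genes in a WGD descendant.

    Returns a list of runs; each run is a dict with the run's genes in
    reading order, its length, and its flanking duplicated genes (gene id
    and the flank's adjacent extremity), or None at a chromosome end.
    """
    orders = _genome_orders(T, None)
    copy_orders = _copy_orders(orders)
    dup = _duplicated_keys(copy_orders)
    runs = []
    for chrom in copy_orders:
        i = 0
        row = list(chrom)
        while i < len(row):
            (key, _c), _s = row[i]
            if key in dup:
                i += 1
                continue
            j = i
            while j < len(row) and row[j][0][0] not in dup:
                j += 1
            run_genes = [(lc[0], s) for lc, s in row[i:j]]
            left = None
            if i > 0:
                (lk, lc), ls = row[i - 1]
                left = (lk, lc, "h" if ls > 0 else "t")
            right = None
            if j < len(row):
                (rk, rc), rs = row[j]
                right = (rk, rc, "t" if rs > 0 else "h")
            runs.append(
                {
                    "genes": run_genes,
                    "length": j - i,
                    "left": left,
                    "right": right,
                }
            )
            i = j
    return runs


def fractionation_correction(T: Genome) -> float:
    """Crude overcount correction: sum of s/3 over single-copy runs s > 3.

    Consolidated single-copy runs enter the doubled ancestor with a partly
    random internal order, inflating the descendant-to-ancestor distance
    by roughly one rearrangement per added breakpoint; runs of length at
    most 3 are left uncorrected.
    """
    if not T.is_wgd_descendant:
        raise ValueError(f"genome {T.name!r} is not flagged as a WGD descendant")
    return sum(
        r["length"] / 3.0 for r in single_copy_runs(T) if r["length"] > 3
    )


def reinsert_single_copy_runs(half: Genome, T: Genome, name: str | None = None) -> Genome:
    """Double ``half`` and re-insert T's single-copy runs next to both copies.

    Each maximal run of single-copy genes is attached at the extremity of
    a flanking duplicated gene g (the left flank when available), in both
    halves of the doubled ancestor, so the insertion does not change the
    DCJ distance.  When both copies of g carry runs at the same extremity,
    the runs are consolidated (copy-1 run first) and the merged run is
    placed at both sites.  Runs with no duplicated flank become their own
    fragment in each half.
    """
    if not T.is_wgd_descendant:
        raise ValueError(f"genome {T.name!r} is not flagged as a WGD descendant")
    runs = single_copy_runs(T)
    # attachments[(gene_key, extremity)] -> list (copy_index, leaving_sequence)
    attachments: dict = {}
    loose: list = []
    for run in runs:
        if run["left"] is not None:
            gk, gc, ext = run["left"]
            leaving = run["genes"]
        elif run["right"] is not None:
            gk, gc, ext = run["right"]
            leaving = [(k, -s) for k, s in reversed(run["genes"])]
        else:
            loose.append(run["genes"])
            continue
        attachments.setdefault((gk, ext), []).append((gc, leaving))

    merged: dict = {}
    for site, entries in attachments.items():
        entries.sort(key=lambda e: e[0])  # copy-1 run first, then copy-2
        merged[site] = [g for _c, leaving in entries for g in leaving]

    half_orders = _genome_orders(half, None)
    out_chroms = []
    for copy in (1, 2):
        for chrom in half_orders:
            row: list = []
            for key, sign in chrom:
                after = (sign > 0)
                pre = merged.get((key, "t" if after else "h"))
                post = merged.get((key, "h" if after else "t"))
                if pre:  # incoming side: reversed, negated
                    row.extend((k, -s * 1) for k, s in reversed(pre))
                row.append((key, sign))
                if post:
                    row.extend(post)
            out_chroms.append((copy, row))
        for seq in loose:
            out_chroms.append((copy, list(seq)))

    name = name or f"A_{T.name}"
    chroms = []
    assignment = {}
    for copy, row in out_chroms:
        genes = tuple((f"{k}|{copy}", s) for k, s in row)
        for k, _s in row:
            assignment[f"{k}|{copy}"] = k
        chroms.append(Chromosome(genes, is_fragment=True))
    genome = Genome(name, chroms, is_wgd_descendant=True)
    return genome.with_orthosets(assignment)


# ---------------------------------------------------------------------------
# small phylogeny
# ---------------------------------------------------------------------------


@dataclass
class SmallPhylogenyResult:
    ancestors: dict  # node -> Genome (doubled ancestors incl. re-inserted runs)
    branch_lengths: dict  # (a, b) sorted tuple -> {"raw", "fragment_corrected", "corrected"}
    sweep_totals: list  # raw total per improvement sweep (incl. initial)
    total: float = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(v["raw"] for v in self.branch_lengths.values())

    @property
    def corrected_total(self) -> float:
        return sum(v["corrected"] for v in self.branch_lengths.values())


def _content_from_leaf_orthosets(tree: PhyloTree, leaf_genomes) -> ContentAssignment:
    members: dict = {}
    for name, g in leaf_genomes.items():
        for os_id in g.orthoset_ids():
            members.setdefault(os_id, set()).add((name, os_id))
    osets = [
        OrthologySet(id=os_id, genes=frozenset(genes))
        for os_id, genes in members.items()
    ]
    return assign_content(tree, osets)


class SmallPhylogenySolver:
    """Initial solution plus iterative median improvement on a fixed tree."""

    def __init__(
        self,
        tree: PhyloTree,
        leaf_genomes: Mapping[str, Genome],
        content: ContentAssignment | None = None,
    ) -> None:
        self.tree = tree
        self.leaves = dict(leaf_genomes)
        missing = set(tree.leaves) - set(self.leaves)
        if missing:
            raise ValueError(f"no genome for leaves: {sorted(missing)}")
        self.content = content or _content_from_leaf_orthosets(tree, self.leaves)
        self.adjacency = tree.augmented_adjacency()
        self.wgd_nodes = {
            tree.doubled_ancestor_name(leaf): leaf for leaf in tree.wgd_leaves
        }
        self.node_orders: dict = {}
        self.node_content: dict = {}
        for leaf, genome in self.leaves.items():
            orders = genome.signed_orders("orthoset")
            self.node_orders[leaf] = orders
            self.node_content[leaf] = _orders_keys(orders)
        for anc in tree.ancestors:
            self.node_content[anc] = set(self.content[anc])
        for a_node, leaf in self.wgd_nodes.items():
            self.integrate_wgd(leaf)
        self.ancestor_genomes: dict = {}

    def integrate_wgd(self, descendant: str) -> str:
        """Set up the doubled-ancestor node for a WGD descendant leaf."""
        if descendant not in self.tree.wgd_leaves:
            raise ValueError(
                f"leaf {descendant!r} is not annotated as a WGD descendant"
            )
        genome = self.leaves[descendant]
        if not genome.is_wgd_descendant:
            raise ValueError(
                f"genome {descendant!r} is not flagged as a WGD descendant"
            )
        a_node = self.tree.doubled_ancestor_name(descendant)
        copy_orders = _copy_orders(self.node_orders[descendant])
        self.node_content[a_node] = _duplicated_keys(copy_orders)
        return a_node

    # -- branch machinery ----------------------------------------------

    def _branch_spec(self, node: str, neighbor: str):
        if neighbor not in self.node_orders:
            return None
        orders = self.node_orders[neighbor]
        if node in self.wgd_nodes and neighbor == self.wgd_nodes[node]:
            return ("double", f"{node}~{neighbor}", _copy_orders(orders))
        return ("simple", f"{node}~{neighbor}", orders)

    def _solve_node(self, node: str) -> list:
        if not self.node_content[node]:
            return []
        specs = []
        for nb in sorted(self.adjacency[node]):
            spec = self._branch_spec(node, nb)
            if spec is not None:
                specs.append(spec)
        if not specs:
            return []
        genome, solver = construct_ancestor(
            specs, self.node_content[node], name=node
        )
        orders = solver.ancestor_orders()
        return orders

    def _branch_raw(self, a: str, b: str) -> int:
        """Raw DCJ length of branch (a, b) under current orders."""
        if a not in self.node_orders or b not in self.node_orders:
            return 0
        # WGD branch: descendant vs doubled ancestor
        for node, leaf in ((a, b), (b, a)):
            if node in self.wgd_nodes and leaf == self.wgd_nodes[node]:
                return self._doubled_branch_raw(node, leaf)
        o1, o2 = self.node_orders[a], self.node_orders[b]
        common = _orders_keys(o1) & _orders_keys(o2)
        r1 = [r for r in ([(l, s) for l, s in c if l in common] for c in o1) if r]
        r2 = [r for r in ([(l, s) for l, s in c if l in common] for c in o2) if r]
        return dcj_distance_orders(r1, r2)

    def _doubled_branch_raw(self, a_node: str, leaf: str) -> int:
        half = Genome(
            a_node,
            [
                Chromosome(tuple((str(k), s) for k, s in c), is_fragment=True)
                for c in self.node_orders[a_node]
            ],
        ).with_orthosets(
            {str(k): k for k in _orders_keys(self.node_orders[a_node])}
        )
        return doubled_distance(self.leaves[leaf], half)

    def _total(self) -> float:
        return float(
            sum(self._branch_raw(a, b) for a, b in self._edges())
        )

    def _edges(self) -> list:
        out = set()
        for a in self.adjacency:
            for b in self.adjacency[a]:
                out.add(tuple(sorted((a, b))))
        return sorted(out)

    # -- solving --------------------------------------------------------

    def initialize(self) -> None:
        """Progressive construction from the leaves inward."""
        todo = [n for n in self.adjacency if n not in self.node_orders]
        while todo:
            todo.sort(
                key=lambda n: (
                    -sum(nb in self.node_orders for nb in self.adjacency[n]),
                    n,
                )
            )
            node = todo.pop(0)
            self.node_orders[node] = self._solve_node(node)

    def sweep(self) -> float:
        """One pass of median improvement over every ancestral node."""
        for node in sorted(n for n in self.adjacency if n not in self.leaves):
            nbs = sorted(self.adjacency[node])
            before = sum(self._branch_raw(node, nb) for nb in nbs)
            old = self.node_orders[node]
            self.node_orders[node] = self._solve_node(node)
            after = sum(self._branch_raw(node, nb) for nb in nbs)
            if after > before:
                self.node_orders[node] = old
        return self._total()

    def run(self, max_sweeps: int = 25) -> SmallPhylogenyResult:
        self.initialize()
        totals = [self._total()]
        for _ in range(max_sweeps):
            total = self.sweep()
            totals.append(total)
            if total >= totals[-2]:
                break
        return self._result(totals)

    # -- reporting ------------------------------------------------------

    def _node_genome(self, node: str) -> Genome:
        chroms = [
            Chromosome(tuple((str(k), s) for k, s in c), is_fragment=True)
            for c in self.node_orders[node]
        ]
        g = Genome(node, chroms)
        return g.with_orthosets({str(k): k for k in _orders_keys(self.node_orders[node])})

    def _result(self, totals: list) -> SmallPhylogenyResult:
        ancestors = {}
        for node in self.adjacency:
            if node in self.leaves:
                continue
            half = self._node_genome(node)
            if node in self.wgd_nodes:
                ancestors[node] = reinsert_single_copy_runs(
                    half, self.leaves[self.wgd_nodes[node]], name=node
                )
            else:
                ancestors[node] = half
        branch_lengths = {}
        for a, b in self._edges():
            raw = self._branch_raw(a, b)
            frag = self._fragment_corrected(a, b, raw)
            corrected = float(frag)
            # fractionation correction applies to the branch from the
            # doubled ancestor into the rest of the tree
            for node in (a, b):
                other = b if node == a else a
                if node in self.wgd_nodes and other != self.wgd_nodes[node]:
                    corrected = max(
                        0.0,
                        corrected
                        - fractionation_correction(
                            self.leaves[self.wgd_nodes[node]]
                        ),
                    )
            branch_lengths[(a, b)] = {
                "raw": raw,
                "fragment_corrected": frag,
                "corrected": corrected,
            }
        return SmallPhylogenyResult(ancestors, branch_lengths, totals)

    def _fragment_corrected(self, a: str, b: str, raw: int) -> int:
        for node, leaf in ((a, b), (b, a)):
            if node in self.wgd_nodes and leaf == self.wgd_nodes[node]:
                return raw  # no fragment correction on the halving branch
        o1, o2 = self.node_orders[a], self.node_orders[b]
        common = _orders_keys(o1) & _orders_keys(o2)
        r1 = [r for r in ([(l, s) for l, s in c if l in common] for c in o1) if r]
        r2 = [r for r in ([(l, s) for l, s in c if l in common] for c in o2) if r]
        if not r1 and not r2:
            return 0
        n_prime, kappa, t1t1, t2t2 = _decompose(r1, r2)
        return max(0, (n_prime - kappa) - abs(t1t1 - t2t2))


def small_phylogeny(
    tree: PhyloTree,
    leaf_genomes: Mapping[str, Genome],
    content: ContentAssignment | None = None,
    max_sweeps: int = 25,
) -> SmallPhylogenyResult:
    """Reconstruct all ancestral gene orders on a fixed unrooted tree.

    A progressive leaf-inward pass provides the initial ancestors; each
    ancestral node is then revisited as a median problem, a new median
    being accepted whenever its three branch lengths sum to no more than
    the current ones, until a full sweep no longer decreases the total
    tree length.
    """
    solver = SmallPhylogenySolver(tree, leaf_genomes, content)
    return solver.run(max_sweeps=max_sweeps)


# ---------------------------------------------------------------------------
# block validation
# ---------------------------------------------------------------------------


def block_integrity(
    blocks: PairwiseHomologyTable,
    ancestor: Genome,
    gene_to_orthoset: Mapping[str, Hashable],
    min_block_size: int = 1,
) -> list:
    """Integrity of pairwise synteny blocks inside a reconstructed ancestor.

    For each block, the genes (from the table's A side) are mapped to the
    ancestor via their orthology sets.  ``breaks`` counts consecutive
    block gene pairs that are no longer adjacent among the block's genes
    in the ancestor (a block split across fragments breaks at the split);
    ``displacement`` is the mean absolute rank shift of the block's genes
    between block order and ancestor order, taking the better of the two
    ancestor orientations.  Blocks with fewer than two genes in the
    ancestor are skipped.
    """
    present = {}
    for gid in ancestor.gene_ids():
        os_id = ancestor.genes[gid].orthoset_id
        present[os_id if os_id is not None else gid] = gid
    # ancestor position of each gene id
    pos = {}
    for ci, chrom in enumerate(ancestor.chromosomes):
        for pi, (gid, _s) in enumerate(chrom.genes):
            pos[gid] = (ci, pi)

    out = []
    for block_id, rows in sorted(blocks.blocks(min_block_size).items(), key=lambda kv: str(kv[0])):
        order = []
        for gene_a in rows["gene_a"]:
            os_id = gene_to_orthoset.get(gene_a)
            if os_id is None or os_id not in present:
                continue
            gid = present[os_id]
            if gid in pos:
                order.append(gid)
        if len(order) < 2:
            continue
        block_pos = {g: i for i, g in enumerate(order)}
        # ancestor order restricted to the block's genes
        restricted = [
            gid
            for chrom in ancestor.chromosomes
            for gid, _s in chrom.genes
            if gid in block_pos
        ]
        frag_of = {g: pos[g][0] for g in order}
        rank = {g: i for i, g in enumerate(restricted)}
        breaks = 0
        for g1, g2 in zip(order, order[1:]):
            if frag_of[g1] != frag_of[g2] or abs(rank[g1] - rank[g2]) != 1:
                breaks += 1
        fwd = sum(abs(block_pos[g] - rank[g]) for g in order) / len(order)
        n = len(restricted)
        rev = sum(
            abs(block_pos[g] - (n - 1 - rank[g])) for g in order
        ) / len(order)
        out.append(
            {
                "block_id": block_id,
                "n_genes": len(rows),
                "n_in_ancestor": len(order),
                "breaks": breaks,
                "displacement": min(fwd, rev),
            }
        )
    return out
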