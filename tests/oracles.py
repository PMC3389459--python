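"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the breakpoint-graph machinery of the package:
the DCJ oracle searches over genomes represented as bare adjacency sets,
applying every possible double-cut-and-join rewiring (including ones that
pass through circular intermediates), and the median/partition oracles
enumerate candidate solutions exhaustively.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

from orthopath.dcj import dcj_distance_orders

# ---------------------------------------------------------------------------
# genomes as adjacency sets
# ---------------------------------------------------------------------------


def adjacency_state(orders) -> frozenset:
    """A genome as the set of its adjacencies (telomeres implicit)."""
    adjs = set()
    for chrom in orders:
        verts = []
        for label, sign in chrom:
            ends = (("t", "h") if sign > 0 else ("h", "t"))
            verts.append((label, ends[0]))
            verts.append((label, ends[1]))
        for i in range(1, len(verts) - 1, 2):
            adjs.add(frozenset((verts[i], verts[i + 1])))
    return frozenset(adjs)


def extremities(orders) -> frozenset:
    return frozenset(
        (label, e) for chrom in orders for label, _s in chrom for e in ("t", "h")
    )


def dcj_neighbors(state: frozenset, ext: frozenset):
    """All genomes one DCJ operation away (circular intermediates allowed)."""
    adjs = sorted(state, key=lambda a: sorted(map(repr, a)))
    used = {e for adj in state for e in adj}
    free = sorted(ext - used)
    # two adjacencies: two rewirings
    for A, B in combinations(adjs, 2):
        a, b = sorted(A)
        c, d = sorted(B)
        base = state - {A, B}
        yield base | {frozenset((a, c)), frozenset((b, d))}
        yield base | {frozenset((a, d)), frozenset((b, c))}
    for A in adjs:
        a, b = sorted(A)
        base = state - {A}
        # adjacency + telomere
        for c in free:
            yield base | {frozenset((a, c))}
            yield base | {frozenset((b, c))}
        # split an adjacency into two telomeres
        yield base
    # join two telomeres
    for a, b in combinations(free, 2):
        yield state | {frozenset((a, b))}


def bfs_dcj_distance(o1, o2, limit: int) -> int | None:
    """Exact DCJ distance by bidirectional breadth-first search.

    Returns the minimum number of operations if it is <= ``limit``, else
    None.  Both genomes must carry the same gene labels.
    """
    ext = extremities(o1)
    assert ext == extremities(o2), "gene content differs"
    s, t = adjacency_state(o1), adjacency_state(o2)
    if s == t:
        return 0
    dist_f = {s: 0}
    dist_b = {t: 0}
    frontier_f, frontier_b = {s}, {t}
    df = db = 0
    best = None
    while df + db < limit:
        if len(frontier_f) <= len(frontier_b):
            frontier, dist_here, dist_other = frontier_f, dist_f, dist_b
            df += 1
            level = df
            forward = True
        else:
            frontier, dist_here, dist_other = frontier_b, dist_b, dist_f
            db += 1
            level = db
            forward = False
        new = set()
        for st in frontier:
            for nb in dcj_neighbors(st, ext):
                if nb in dist_here:
                    continue
                dist_here[nb] = level
                new.add(nb)
                if nb in dist_other:
                    cand = level + dist_other[nb]
                    if best is None or cand < best:
                        best = cand
        if forward:
            frontier_f = new
        else:
            frontier_b = new
        if not new:
            break
        if best is not None and best <= df + db:
            break
    return best if best is not None and best <= limit else None


def full_distance_map(o1) -> dict:
    """Distances from one genome to every reachable adjacency state."""
    ext = extremities(o1)
    s = adjacency_state(o1)
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for st in frontier:
            for nb in dcj_neighbors(st, ext):
                if nb not in dist:
                    dist[nb] = dist[st] + 1
                    nxt.append(nb)
        frontier = nxt
    return dist


# ---------------------------------------------------------------------------
# exhaustive enumeration of small genomes, medians
# ---------------------------------------------------------------------------


def _canonical(orders) -> frozenset:
    out = set()
    for chrom in orders:
        rev = tuple((g, -s) for g, s in reversed(chrom))
        out.add(min(tuple(chrom), rev))
    return frozenset(out)


def enumerate_genomes(labels) -> list:
    """Every multichromosomal signed genome over ``labels`` (as orders)."""
    labels = list(labels)
    n = len(labels)
    seen = set()
    out = []
    for perm in permutations(labels):
        for signs in product((1, -1), repeat=n):
            seq = list(zip(perm, signs))
            for mask in range(2 ** (n - 1)) if n > 1 else (0,):
                chroms = []
                start = 0
                for i in range(1, n):
                    if mask & (1 << (i - 1)):
                        chroms.append(tuple(seq[start:i]))
                        start = i
                chroms.append(tuple(seq[start:]))
                key = _canonical(chroms)
                if key not in seen:
                    seen.add(key)
                    out.append([tuple(c) for c in chroms])
    return out


def exhaustive_median_total(inputs, candidates=None) -> int:
    """Minimum of sum of DCJ distances over all candidate median genomes."""
    if candidates is None:
        labels = sorted({l for o in inputs for c in o for l, _s in c})
        candidates = enumerate_genomes(labels)
    best = None
    for cand in candidates:
        total = sum(dcj_distance_orders(cand, o) for o in inputs)
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# exhaustive orthology-set partition optimum
# ---------------------------------------------------------------------------


def _partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    head, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [head]] + part[i + 1 :]
        yield part + [[head]]


def set_objective(parts, wgd=()) -> int:
    """Sum over parts of |part| * (genome count with WGD allowance)."""
    total = 0
    for part in parts:
        counts: dict = {}
        for genome, _g in part:
            counts[genome] = counts.get(genome, 0) + 1
        c = sum(min(n, 2 if g in wgd else 1) for g, n in counts.items())
        total += len(part) * c
    return total


def exhaustive_partition_optimum(G, wgd=()) -> int:
    """Best achievable objective over edge-deletion outcomes.

    Enumerates all partitions of the component's vertices into parts that
    are connected in the reported graph and free of disallowed paralogy,
    exactly the end states reachable by deleting edges.
    """
    import networkx as nx

    nodes = sorted(G.nodes)
    best = None
    for parts in _partitions(nodes):
        ok = True
        for part in parts:
            counts: dict = {}
            for genome, _g in part:
                counts[genome] = counts.get(genome, 0) + 1
            if any(n > (2 if g in wgd else 1) for g, n in counts.items()):
                ok = False
                break
            if len(part) > 1 and not nx.is_connected(G.subgraph(part)):
                ok = False
                break
        if not ok:
            continue
        val = set_objective(parts, wgd)
        if best is None or val > best:
            best = val
    return best
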