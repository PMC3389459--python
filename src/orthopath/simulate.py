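"""Seeded generators of tree-evolved genomes with known ground truth.

The generator evolves a root genome down a fixed unrooted tree (rooted for
simulation at the tree's center), applying a configured number of random
DCJ operations per branch, optional per-branch gene loss (producing
unequal gene content), and — on branches leading to WGD descendants —
whole-genome doubling followed by fractionation, the run-length deletion
of one member of duplicate pairs.  Pairwise homology tables are emitted
from the true gene families, grouped into colinear blocks, optionally
corrupted by dropped true pairs and spurious (paralogy-creating) pairs.

Every stage is deterministic under the configured seed.  Transpositions
are excluded from the default operation mix: the DCJ metric counts a
transposition as two operations, which would blur the guarantee that the
true distance never exceeds the number of operations drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genomes import Chromosome, Genome
from .homology import COLUMNS, PairwiseHomologyTable
from .trees import PhyloTree

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "random_genome",
    "apply_random_dcj",
    "simulate_wgd",
    "simulate_tree",
    "emit_homology_tables",
]

DEFAULT_TREE = "(G1,(G2,(G3,(G4,(G5,G6)))));"


@dataclass
class SimulationConfig:
    """Study conditions for one simulated data set.

    Defaults follow the regime in which the reconstruction heuristic is
    known to be accurate: about 0.12 operations per gene per branch, with
    fractionation deleting geometric runs of mean length 2.5 duplicates.
    """

    n_genes: int = 1000
    n_chromosomes: int = 5
    tree: str = DEFAULT_TREE
    dn_ratio: float = 0.12
    ops_per_branch: int | None = None  # overrides dn_ratio when set
    loss_rate: float = 0.0
    wgd_ops_split: float = 0.5  # share of WGD-branch ops before doubling
    fractionation_loss: float = 0.5  # fraction of families reduced to 1 copy
    fractionation_run_mean: float = 2.5
    noise_rate: float = 0.0
    op_weights: dict | None = None  # defaults to an inversion-dominated mix
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("loss_rate", "noise_rate", "fractionation_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < self.n_chromosomes:
            raise ValueError("need at least one gene per chromosome")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def branch_ops(self) -> int:
        if self.ops_per_branch is not None:
            return int(self.ops_per_branch)
        return int(round(self.dn_ratio * self.n_genes))


@dataclass
class SimulationResult:
    config: SimulationConfig
    tree: PhyloTree
    leaf_genomes: dict
    true_ancestors: dict  # node -> Genome (incl. doubled WGD ancestors)
    branch_ops: dict  # (a, b) sorted -> operations drawn on that branch
    families: dict  # family id -> set of (genome, gene_id)
    tables: list = field(default_factory=list)

    @property
    def total_ops(self) -> int:
        return sum(self.branch_ops.values())


# ---------------------------------------------------------------------------
# genomes and rearrangements
# ---------------------------------------------------------------------------


def _orders(g: Genome):
    return [list(c.genes) for c in g.chromosomes]


def _genome(name: str, orders, wgd: bool = False) -> Genome:
    return Genome(
        name,
        [Chromosome(tuple(row)) for row in orders if row],
        is_wgd_descendant=wgd,
    )


def random_genome(n: int, chromosomes: int, seed: int) -> Genome:
    """Identity-ordered genes g1..gn split into chromosomes at random cuts."""
    if not 1 <= chromosomes <= n:
        raise ValueError(f"cannot place {n} genes on {chromosomes} chromosomes")
    rng = np.random.default_rng(seed)
    cuts = (
        sorted(rng.choice(np.arange(1, n), size=chromosomes - 1, replace=False))
        if chromosomes > 1
        else []
    )
    bounds = [0, *cuts, n]
    orders = [
        [(f"g{i + 1}", 1) for i in range(a, b)]
        for a, b in zip(bounds, bounds[1:])
    ]
    return _genome("random", orders)


DEFAULT_OP_WEIGHTS = {
    "inversion": 0.8,
    "translocation": 0.15,
    "fusion": 0.025,
    "fission": 0.025,
}


def _feasible_ops(orders) -> list[str]:
    ops = []
    if any(len(c) >= 2 for c in orders):
        ops.append("inversion")
        ops.append("fission")
    if len(orders) >= 2:
        ops.append("translocation")
        ops.append("fusion")
    return ops


def _rand_op(orders, rng, weights=None) -> tuple[list, dict]:
    ops = _feasible_ops(orders)
    if not ops:
        return orders, {"op": "none"}
    w = weights or DEFAULT_OP_WEIGHTS
    probs = [w.get(op, 0.0) for op in ops]
    total = sum(probs)
    if total <= 0:
        probs = [1.0] * len(ops)
        total = float(len(ops))
    probs = [p / total for p in probs]
    op = ops[int(rng.choice(len(ops), p=probs))]
    orders = [list(c) for c in orders]
    if op == "inversion":
        cands = [i for i, c in enumerate(orders) if len(c) >= 2]
        ci = cands[int(rng.integers(len(cands)))]
        c = orders[ci]
        while True:
            i = int(rng.integers(len(c)))
            j = int(rng.integers(len(c)))
            i, j = min(i, j), max(i, j)
            if not (i == 0 and j == len(c) - 1):
                break
        c[i : j + 1] = [(g, -s) for g, s in reversed(c[i : j + 1])]
        log = {"op": op, "chrom": ci, "span": (i, j)}
    elif op == "fission":
        cands = [i for i, c in enumerate(orders) if len(c) >= 2]
        ci = cands[int(rng.integers(len(cands)))]
        c = orders.pop(ci)
        cut = 1 + int(rng.integers(len(c) - 1))
        orders.extend([c[:cut], c[cut:]])
        log = {"op": op, "chrom": ci, "cut": cut}
    elif op == "fusion":
        i, j = rng.choice(len(orders), size=2, replace=False)
        a, b = orders[int(i)], orders[int(j)]
        if rng.integers(2):
            a = [(g, -s) for g, s in reversed(a)]
        if rng.integers(2):
            b = [(g, -s) for g, s in reversed(b)]
        merged = a + b
        orders = [c for k, c in enumerate(orders) if k not in (int(i), int(j))]
        orders.append(merged)
        log = {"op": op}
    else:  # translocation
        i, j = rng.choice(len(orders), size=2, replace=False)
        a, b = orders[int(i)], orders[int(j)]
        while True:
            ca = int(rng.integers(len(a) + 1))
            cb = int(rng.integers(len(b) + 1))
            if not (ca == len(a) and cb == len(b)) and not (ca == 0 and cb == 0):
                break
        if rng.integers(2):
            na = a[:ca] + b[cb:]
            nb = b[:cb] + a[ca:]
        else:
            na = a[:ca] + [(g, -s) for g, s in reversed(b[:cb])]
            nb = [(g, -s) for g, s in reversed(a[ca:])] + b[cb:]
        orders[int(i)], orders[int(j)] = na, nb
        orders = [c for c in orders if c]
        log = {"op": op}
    return orders, log


def apply_random_dcj(
    g: Genome, k: int, seed: int, weights: dict | None = None
) -> tuple[Genome, list]:
    """Apply ``k`` random feasible operations; the true distance is <= k.

    The default operation mix is dominated by inversions (with occasional
    translocations, fusions and fissions), so that at low operation
    density the true distance is almost always exactly ``k``; a uniform or
    custom mix can be requested through ``weights``.
    """
    rng = np.random.default_rng(seed)
    orders = _orders(g)
    logs = []
    for _ in range(int(k)):
        orders, log = _rand_op(orders, rng, weights)
        logs.append(log)
    return _genome(g.name, orders, g.is_wgd_descendant), logs


# ---------------------------------------------------------------------------
# WGD and fractionation
# ---------------------------------------------------------------------------


def simulate_wgd(
    g: Genome,
    fractionation_loss: float = 0.5,
    run_mean: float = 2.5,
    seed: int = 0,
    extra_ops: int = 0,
) -> Genome:
    """Double a genome, rearrange, then fractionate duplicate runs.

    Doubling suffixes the two copies ``.a``/``.b``.  Each fractionation
    event picks a random still-duplicated gene and deletes a run of
    consecutive genes (geometric length, mean ``run_mean``) from that
    homeolog, skipping genes whose other copy is already gone, until the
    requested fraction of families is single-copy.  At least one copy of
    every gene always survives.
    """
    rng = np.random.default_rng(seed)
    doubled = [
        [(f"{gid}.{suffix}", s) for gid, s in c.genes]
        for suffix in ("a", "b")
        for c in g.chromosomes
    ]
    orders = doubled
    if extra_ops:
        for _ in range(int(extra_ops)):
            orders, _log = _rand_op(orders, rng)

    def family(gid: str) -> str:
        return gid.rsplit(".", 1)[0]

    n_families = len({family(gid) for c in orders for gid, _ in c})
    target = int(round(fractionation_loss * n_families))
    p = 1.0 / run_mean  # geometric on {1, 2, ...} with mean run_mean

    def counts():
        cnt: dict[str, int] = {}
        for c in orders:
            for gid, _ in c:
                cnt[family(gid)] = cnt.get(family(gid), 0) + 1
        return cnt

    cnt = counts()
    guard = 0
    while sum(1 for v in cnt.values() if v == 1) < target and guard < 50 * n_families:
        guard += 1
        ci = int(rng.integers(len(orders)))
        c = orders[ci]
        start = int(rng.integers(len(c)))
        run = int(rng.geometric(p))
        removed = []
        for k in range(start, min(start + run, len(c))):
            gid, _s = c[k]
            if cnt[family(gid)] == 2:
                removed.append(k)
                cnt[family(gid)] -= 1
            else:
                break
        if not removed:
            continue
        orders[ci] = [x for k, x in enumerate(c) if k not in set(removed)]
        orders = [c for c in orders if c]
    return _genome(g.name, orders, wgd=True)


# ---------------------------------------------------------------------------
# tree simulation
# ---------------------------------------------------------------------------


def simulate_tree(config: SimulationConfig) -> SimulationResult:
    """Evolve genomes down the configured tree, logging all ground truth."""
    from .trees import read_tree

    tree = config.tree if isinstance(config.tree, PhyloTree) else read_tree(config.tree)
    rng = np.random.default_rng(config.seed)
    root_node = tree.center()
    root = random_genome(
        config.n_genes, config.n_chromosomes, int(rng.integers(2**31))
    )

    genomes: dict[str, Genome] = {root_node: _genome(root_node, _orders(root))}
    true_ancestors: dict[str, Genome] = {}
    leaf_genomes: dict[str, Genome] = {}
    branch_ops: dict[tuple, int] = {}

    stack = [(root_node, None)]
    visited = {root_node}
    k = config.branch_ops
    while stack:
        node, _parent = stack.pop(0)
        g = genomes[node]
        if node in tree.leaves:
            continue
        for nb in sorted(tree.neighbors(node)):
            if nb in visited:
                continue
            visited.add(nb)
            child_seed = int(rng.integers(2**31))
            if nb in tree.wgd_leaves:
                pre = int(round(k * config.wgd_ops_split))
                post = k - pre
                before, _ = apply_random_dcj(g, pre, child_seed, config.op_weights)
                a_node = tree.doubled_ancestor_name(nb)
                doubled_orders = [
                    [(f"{gid}.{sfx}", s) for gid, s in c]
                    for sfx in ("a", "b")
                    for c in _orders(before)
                ]
                true_ancestors[a_node] = _genome(a_node, doubled_orders, wgd=True)
                child = simulate_wgd(
                    _genome(nb, _orders(before)),
                    fractionation_loss=config.fractionation_loss,
                    run_mean=config.fractionation_run_mean,
                    seed=int(rng.integers(2**31)),
                    extra_ops=post,
                )
                branch_ops[tuple(sorted((node, nb)))] = k
            else:
                child, _ = apply_random_dcj(
                    _genome(nb, _orders(g)), k, child_seed, config.op_weights
                )
                branch_ops[tuple(sorted((node, nb)))] = k
                if config.loss_rate > 0:
                    child = _apply_loss(child, config.loss_rate, rng)
            genomes[nb] = child
            if nb in tree.leaves:
                leaf_genomes[nb] = child
            else:
                stack.append((nb, node))

    for anc in tree.ancestors:
        true_ancestors[anc] = genomes[anc]

    families: dict[str, set] = {}
    for name, g in leaf_genomes.items():
        for gid in g.gene_ids():
            fam = gid.split(".")[0]
            families.setdefault(fam, set()).add((name, gid))

    # label every leaf genome with its true family as orthoset id
    labelled = {}
    for name, g in leaf_genomes.items():
        labelled[name] = g.with_orthosets(
            {gid: gid.split(".")[0] for gid in g.gene_ids()}
        )

    result = SimulationResult(
        config=config,
        tree=tree,
        leaf_genomes=labelled,
        true_ancestors=true_ancestors,
        branch_ops=branch_ops,
        families=families,
    )
    result.tables = emit_homology_tables(
        labelled, config.noise_rate, int(rng.integers(2**31))
    )
    return result


def _apply_loss(g: Genome, rate: float, rng) -> Genome:
    orders = []
    kept_any = False
    for c in g.chromosomes:
        row = [x for x in c.genes if rng.random() >= rate]
        if row:
            orders.append(row)
            kept_any = True
    if not kept_any:  # pathological high rates: keep one gene
        orders = [[g.chromosomes[0].genes[0]]]
    return _genome(g.name, orders, g.is_wgd_descendant)


# ---------------------------------------------------------------------------
# homology tables
# ---------------------------------------------------------------------------


def _positions(g: Genome) -> dict:
    pos = {}
    for ci, c in enumerate(g.chromosomes, start=1):
        for pi, (gid, s) in enumerate(c.genes, start=1):
            pos[gid] = (f"c{ci}", pi, "+" if s > 0 else "-")
    return pos


def emit_homology_tables(
    leaf_genomes: Mapping[str, Genome],
    noise_rate: float = 0.0,
    seed: int = 0,
) -> list[PairwiseHomologyTable]:
    """True ortholog pairs per genome pair, blocked by colinear runs.

    Genes must carry their family as orthoset id.  With ``noise_rate`` q,
    each true pair is dropped with probability q/2 and round(q/2 * n_true)
    spurious pairs between random genes are added, each in its own
    single-pair block (spurious matches masquerade as tiny blocks).
    """
    rng = np.random.default_rng(seed)
    names = sorted(leaf_genomes)
    tables = []
    for ai in range(len(names)):
        for bi in range(ai + 1, len(names)):
            na, nb = names[ai], names[bi]
            ga, gb = leaf_genomes[na], leaf_genomes[nb]
            fam_b: dict = {}
            for gid, gene in gb.genes.items():
                if gene.orthoset_id is not None:
                    fam_b.setdefault(gene.orthoset_id, []).append(gid)
            pos_a, pos_b = _positions(ga), _positions(gb)
            rows = []
            for ca in ga.chromosomes:
                for gid, _s in ca.genes:
                    fam = ga.genes[gid].orthoset_id
                    if fam is None:
                        continue
                    for gid_b in sorted(fam_b.get(fam, ())):
                        rows.append((gid, gid_b))
            # keep deterministic positional order, then block by colinearity
            rows.sort(key=lambda r: (pos_a[r[0]][0], pos_a[r[0]][1], r[1]))
            kept = [r for r in rows if not (noise_rate and rng.random() < noise_rate / 2)]
            n_spurious = int(round(noise_rate / 2 * len(rows)))
            records = []
            block = 0
            prev = None
            for gid_a, gid_b in kept:
                ca_, pa, sa = pos_a[gid_a]
                cb_, pb, sb = pos_b[gid_b]
                colinear = (
                    prev is not None
                    and ca_ == prev[0]
                    and pa - prev[1] == 1
                    and cb_ == prev[2]
                    and abs(pb - prev[3]) == 1
                )
                if not colinear:
                    block += 1
                records.append(
                    (na, gid_a, ca_, pa, sa, nb, gid_b, cb_, pb, sb, f"b{block}")
                )
                prev = (ca_, pa, cb_, pb)
            all_a = sorted(ga.gene_ids())
            all_b = sorted(gb.gene_ids())
            for si in range(n_spurious):
                gid_a = all_a[int(rng.integers(len(all_a)))]
                gid_b = all_b[int(rng.integers(len(all_b)))]
                block += 1
                ca_, pa, sa = pos_a[gid_a]
                cb_, pb, sb = pos_b[gid_b]
                records.append(
                    (na, gid_a, ca_, pa, sa, nb, gid_b, cb_, pb, sb, f"b{block}")
                )
            df = pd.DataFrame(records, columns=COLUMNS)
            tables.append(PairwiseHomologyTable(na, nb, df))
    return tables
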