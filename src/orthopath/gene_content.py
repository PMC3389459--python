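"""Parsimonious assignment of orthology sets to ancestral nodes.

Presence/absence of each orthology set is treated as a binary character.
Ancestral states minimize gain+loss events on the unrooted tree (small
parsimony); any such labelling satisfies the majority fixed point: a gene
is present in an ancestor exactly when it is present in at least two of
its three adjacent nodes.  Among equally parsimonious labellings, ties are
resolved toward presence at the node chosen as root — the topological
center of the tree — which pushes gains as early (as central) as possible
without committing to a true root.

A WGD descendant's doubled-ancestor node is not part of the binary tree;
it inherits presence for every gene with at least one surviving copy in
the descendant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .omg import OrthologySet
from .trees import PhyloTree

__all__ = ["ContentAssignment", "assign_content", "majority_violations"]

_INF = 1 << 30


@dataclass
class ContentAssignment:
    """node name -> frozenset of orthoset ids present at that node."""

    content: dict

    def __getitem__(self, node: str) -> frozenset:
        return self.content[node]

    def __contains__(self, node: str) -> bool:
        return node in self.content

    def items(self):
        return self.content.items()


def _leaf_presence(
    tree: PhyloTree, orthosets: Iterable[OrthologySet]
) -> dict[str, set]:
    leaves = set(tree.leaves)
    present: dict[str, set] = {leaf: set() for leaf in leaves}
    for oset in orthosets:
        for genome in oset.genomes():
            if genome not in leaves:
                raise ValueError(
                    f"orthology set {oset.id} references {genome!r}, "
                    "which is not a leaf of the tree"
                )
            present[genome].add(oset.id)
    return present


def assign_content(
    tree: PhyloTree, orthosets: Iterable[OrthologySet]
) -> ContentAssignment:
    """Assign each orthology set to the ancestors of an unrooted tree."""
    orthosets = list(orthosets)
    leaf_sets = _leaf_presence(tree, orthosets)

    root = tree.center()
    # rooted traversal structure over the unrooted tree
    parent: dict[str, str | None] = {root: None}
    order: list[str] = [root]
    stack = [root]
    while stack:
        node = stack.pop()
        for nb in sorted(tree.neighbors(node)):
            if nb not in parent:
                parent[nb] = node
                order.append(nb)
                stack.append(nb)
    postorder = order[::-1]
    children: dict[str, list[str]] = {n: [] for n in order}
    for node, par in parent.items():
        if par is not None:
            children[par].append(node)

    ancestors = set(tree.ancestors)
    anc_sets: dict[str, set] = {a: set() for a in ancestors}

    for oset in orthosets:
        oid = oset.id
        # Sankoff up-pass: cost[node][state] over the subtree below node
        cost: dict[str, tuple[int, int]] = {}
        for node in postorder:
            if node in leaf_sets:
                here = oid in leaf_sets[node]
                cost[node] = (_INF if here else 0, 0 if here else _INF)
            else:
                c0 = c1 = 0
                for ch in children[node]:
                    k0, k1 = cost[ch]
                    c0 += min(k0, k1 + 1)
                    c1 += min(k0 + 1, k1)
                cost[node] = (c0, c1)
        # down-pass: assign states, ties toward presence (state 1)
        state: dict[str, int] = {}
        c0, c1 = cost[root]
        state[root] = 1 if c1 <= c0 else 0
        for node in order[1:]:
            k0, k1 = cost[node]
            par_state = state[parent[node]]
            with0 = k0 + (1 if par_state == 1 else 0)
            with1 = k1 + (1 if par_state == 0 else 0)
            state[node] = 1 if with1 <= with0 else 0
        for anc in ancestors:
            if state[anc]:
                anc_sets[anc].add(oid)

    content = {leaf: frozenset(s) for leaf, s in leaf_sets.items()}
    content.update({a: frozenset(s) for a, s in anc_sets.items()})
    # doubled ancestors mirror their WGD descendant's surviving content
    for leaf in tree.wgd_leaves:
        content[tree.doubled_ancestor_name(leaf)] = content[leaf]
    return ContentAssignment(content)


def majority_violations(
    tree: PhyloTree, assignment: ContentAssignment | Mapping[str, frozenset]
) -> list[tuple[str, str]]:
    """(ancestor, orthoset) pairs where the majority rule is not a fixed point.

    Re-evaluates, at every ancestral node of the base tree, the rule "a
    gene is present iff it is present in at least two of the three
    adjacent nodes"; an empty result certifies the fixed point.
    """
    content = (
        assignment.content if isinstance(assignment, ContentAssignment) else assignment
    )
    bad = []
    universe = set()
    for s in content.values():
        universe |= s
    for anc in tree.ancestors:
        nbs = sorted(tree.neighbors(anc))
        for oid in sorted(universe):
            votes = sum(1 for nb in nbs if oid in content[nb])
            present = oid in content[anc]
            if present != (votes >= 2):
                bad.append((anc, oid))
    return bad
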