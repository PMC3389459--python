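"""Unrooted binary phylogenies with WGD-descendant annotations.

Trees are read from Newick.  A leaf whose subtending branch carries a
``[&WGD]`` comment is flagged as the descendant of a whole-genome
duplication; the solver later inserts a "doubled ancestor" node on that
branch.  An unrooted binary tree on N leaves has N-2 ancestral nodes and
2N-3 branches; ancestors are auto-named M1..M(N-2).
"""

from __future__ import annotations

import re
from collections import deque
from pathlib import Path
from typing import Iterable

import dendropy

__all__ = ["PhyloTree", "TreeError", "read_tree"]

_WGD_RE = re.compile(r"\[&\s*WGD\s*\]", re.IGNORECASE)


class TreeError(ValueError):
    """Invalid tree structure or inconsistent leaf set."""


class PhyloTree:
    """Unrooted binary tree: leaves are genome names, ancestors M1..M(N-2)."""

    def __init__(
        self,
        adjacency: dict[str, set[str]],
        wgd_leaves: Iterable[str] = (),
    ) -> None:
        self.adjacency = {n: set(v) for n, v in adjacency.items()}
        self.leaves = sorted(n for n, v in self.adjacency.items() if len(v) == 1)
        self.ancestors = sorted(
            (n for n, v in self.adjacency.items() if len(v) != 1),
            key=_ancestor_sort_key,
        )
        self.wgd_leaves = set(wgd_leaves)
        self._validate()

    def _validate(self) -> None:
        n_leaves = len(self.leaves)
        if n_leaves < 3:
            raise TreeError("tree must have at least 3 leaves")
        for node in self.ancestors:
            if len(self.adjacency[node]) != 3:
                raise TreeError(
                    f"internal node {node!r} has degree "
                    f"{len(self.adjacency[node])}; tree must be binary (unrooted)"
                )
        if len(self.ancestors) != n_leaves - 2:
            raise TreeError("tree is not binary: wrong ancestor count")
        # connectivity + acyclicity: N nodes need N-1 edges and one component
        if len(self.edges()) != len(self.adjacency) - 1:
            raise TreeError("tree has a cycle")
        seen = set()
        stack = [self.leaves[0]]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(self.adjacency[node])
        if len(seen) != len(self.adjacency):
            raise TreeError("tree is not connected")
        missing = self.wgd_leaves - set(self.leaves)
        if missing:
            raise TreeError(f"WGD annotation on unknown leaves: {sorted(missing)}")

    # -- queries --------------------------------------------------------

    def neighbors(self, node: str) -> set[str]:
        return self.adjacency[node]

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            tuple(sorted((a, b))) for a in self.adjacency for b in self.adjacency[a]
            if a < b
        )

    def has_leaf(self, name: str) -> bool:
        return name in self.adjacency and len(self.adjacency[name]) == 1

    def path(self, a: str, b: str) -> list[str]:
        """Nodes on the unique path from ``a`` to ``b`` (inclusive)."""
        prev: dict[str, str] = {a: a}
        queue = deque([a])
        while queue:
            node = queue.popleft()
            if node == b:
                break
            for nb in self.adjacency[node]:
                if nb not in prev:
                    prev[nb] = node
                    queue.append(nb)
        if b not in prev:
            raise TreeError(f"no path between {a!r} and {b!r}")
        out = [b]
        while out[-1] != a:
            out.append(prev[out[-1]])
        return out[::-1]

    def internal_nodes_between(self, leaf_a: str, leaf_b: str) -> int:
        """Number of ancestral nodes on the path between two leaves."""
        return sum(1 for n in self.path(leaf_a, leaf_b) if n in set(self.ancestors))

    def center(self) -> str:
        """A topological center: minimal eccentricity, ties to smaller name.

        Used as the root-free anchor for "as early in the tree as possible"
        tie-breaking in ancestral gene-content assignment.
        """
        best = None
        for node in self.ancestors or self.leaves:
            ecc = self._eccentricity(node)
            key = (ecc, node)
            if best is None or key < best[0]:
                best = (key, node)
        assert best is not None
        return best[1]

    def _eccentricity(self, node: str) -> int:
        dist = {node: 0}
        queue = deque([node])
        while queue:
            cur = queue.popleft()
            for nb in self.adjacency[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + 1
                    queue.append(nb)
        return max(dist.values())

    # -- WGD augmentation ----------------------------------------------

    def doubled_ancestor_name(self, wgd_leaf: str) -> str:
        return f"A_{wgd_leaf}"

    def augmented_adjacency(self) -> dict[str, set[str]]:
        """Adjacency with a doubled-ancestor node spliced into each WGD branch.

        For a WGD descendant T attached to ancestor R, the branch T-R is
        replaced by T-A and A-R, where A is the perfectly doubled ancestor
        immediately after the duplication event.
        """
        adj = {n: set(v) for n, v in self.adjacency.items()}
        for leaf in sorted(self.wgd_leaves):
            (r,) = adj[leaf]
            a = self.doubled_ancestor_name(leaf)
            adj[leaf] = {a}
            adj[r].discard(leaf)
            adj[r].add(a)
            adj[a] = {leaf, r}
        return adj

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PhyloTree({len(self.leaves)} leaves, {len(self.ancestors)} ancestors,"
            f" wgd={sorted(self.wgd_leaves)})"
        )


def _ancestor_sort_key(name: str):
    m = re.fullmatch(r"M(\d+)", name)
    return (0, int(m.group(1)), name) if m else (1, 0, name)


def read_tree(path_or_text: str | Path) -> PhyloTree:
    """Read an unrooted binary Newick tree; ``[&WGD]`` marks WGD leaves."""
    text = str(path_or_text)
    if "(" not in text:
        text = Path(path_or_text).read_text()
    wgd_leaves = {
        m.group(1)
        for m in re.finditer(r"([^\s(),:;\[\]]+)\s*(?::[\d.eE+-]+)?\s*\[&\s*WGD\s*\]", text, re.IGNORECASE)
    }
    clean = _WGD_RE.sub("", text)
    tree = dendropy.Tree.get(
        data=clean, schema="newick", preserve_underscores=True
    )

    adjacency: dict[str, set[str]] = {}
    names: dict[int, str] = {}
    counter = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            if node.taxon is None or not node.taxon.label:
                raise TreeError("unnamed leaf in tree")
            names[id(node)] = node.taxon.label
        else:
            counter += 1
            names[id(node)] = f"M{counter}"
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            a, b = names[id(node)], names[id(child)]
            adjacency.setdefault(a, set()).add(b)
            adjacency.setdefault(b, set()).add(a)

    # A rooted reading of an unrooted tree leaves a degree-2 root: splice
    # it out so every internal node has degree 3.
    root = names[id(tree.seed_node)]
    if len(adjacency.get(root, ())) == 2:
        a, b = sorted(adjacency.pop(root))
        adjacency[a].discard(root)
        adjacency[b].discard(root)
        adjacency[a].add(b)
        adjacency[b].add(a)

    # renumber ancestors deterministically M1.. in traversal order
    internal = [n for n in adjacency if len(adjacency[n]) > 1]
    mapping = {}
    idx = 0
    for n in sorted(internal, key=_ancestor_sort_key):
        idx += 1
        mapping[n] = f"M{idx}"
    adjacency = {
        mapping.get(n, n): {mapping.get(v, v) for v in vs}
        for n, vs in adjacency.items()
    }
    unknown = wgd_leaves - {n for n, v in adjacency.items() if len(v) == 1}
    if unknown:
        raise TreeError(f"[&WGD] tag on non-leaf label(s): {sorted(unknown)}")
    return PhyloTree(adjacency, wgd_leaves)
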