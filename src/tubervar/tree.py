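"""Unrooted trees over sample labels, with canonical newick serialization.

Trees produced by the parsimony search are unrooted and binary (every
internal node has degree 3).  Serialization roots the tree deterministically
so that equal topologies always yield byte-identical newick strings:
the tree is rooted on the internal edge next to the lexicographically
smallest leaf, and children are ordered by the smallest leaf label in their
subtree.
"""

from __future__ import annotations

import io
from typing import Dict, Iterator, List, Set, Tuple

import dendropy


class UnrootedTree:
    """An unrooted tree with labelled leaves, stored as an adjacency map."""

    def __init__(self) -> None:
        self.adj: Dict[int, Set[int]] = {}
        self.labels: Dict[int, str] = {}
        self._next_id = 0

    # -- construction -----------------------------------------------------

    def new_node(self, label: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = set()
        if label is not None:
            self.labels[nid] = label
        return nid

    def add_edge(self, a: int, b: int) -> None:
        self.adj[a].add(b)
        self.adj[b].add(a)

    def remove_edge(self, a: int, b: int) -> None:
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    @classmethod
    def star(cls, labels: List[str]) -> "UnrootedTree":
        """Three or more leaves joined at a single internal node."""
        t = cls()
        center = t.new_node()
        for lab in labels:
            leaf = t.new_node(lab)
            t.add_edge(center, leaf)
        return t

    def copy(self) -> "UnrootedTree":
        t = UnrootedTree()
        t.adj = {k: set(v) for k, v in self.adj.items()}
        t.labels = dict(self.labels)
        t._next_id = self._next_id
        return t

    # -- queries ----------------------------------------------------------

    @property
    def leaves(self) -> List[int]:
        return [n for n in self.adj if n in self.labels]

    @property
    def leaf_labels(self) -> List[str]:
        return sorted(self.labels.values())

    def degree(self, n: int) -> int:
        return len(self.adj[n])

    def edges(self) -> Iterator[Tuple[int, int]]:
        seen = set()
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if (b, a) not in seen:
                    seen.add((a, b))
                    yield (a, b)

    def internal_edges(self) -> List[Tuple[int, int]]:
        return [
            (a, b)
            for a, b in self.edges()
            if a not in self.labels and b not in self.labels
        ]

    def is_binary(self) -> bool:
        return all(
            (n in self.labels and len(nb) == 1) or len(nb) == 3
            for n, nb in self.adj.items()
        )

    def subtree_leaves(self, node: int, parent: int) -> Set[str]:
        """Leaf labels on ``node``'s side of the edge (parent, node)."""
        out: Set[str] = set()
        stack = [(node, parent)]
        while stack:
            n, p = stack.pop()
            if n in self.labels:
                out.add(self.labels[n])
            for c in self.adj[n]:
                if c != p:
                    stack.append((c, n))
        return out

    def splits(self) -> Set[frozenset]:
        """Non-trivial bipartitions induced by internal edges.

        Each split is reported as the frozenset of leaf labels on one fixed
        side (the side not containing the smallest label), so two trees are
        topologically equal iff their split sets are equal.
        """
        all_labels = set(self.labels.values())
        smallest = min(all_labels)
        out = set()
        for a, b in self.internal_edges():
            side = self.subtree_leaves(b, a)
            if smallest in side:
                side = all_labels - side
            out.add(frozenset(side))
        return out

    # -- newick -----------------------------------------------------------

    def _min_leaf(self, node: int, parent: int) -> str:
        return min(self.subtree_leaves(node, parent))

    def _render(self, node: int, parent: int) -> str:
        if node in self.labels:
            return self.labels[node]
        children = sorted(
            (c for c in self.adj[node] if c != parent),
            key=lambda c: self._min_leaf(c, node),
        )
        return "(" + ",".join(self._render(c, node) for c in children) + ")"

    def to_newick(self) -> str:
        labels = list(self.labels.values())
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in tree")
        if len(labels) < 2:
            raise ValueError("need at least two leaves")
        if len(labels) == 2:
            return "(%s,%s);" % tuple(sorted(labels))
        smallest_leaf = next(
            n for n, lab in self.labels.items() if lab == min(labels)
        )
        u = next(iter(self.adj[smallest_leaf]))
        internal_nbrs = [v for v in self.adj[u] if v not in self.labels]
        if not internal_nbrs:
            # star over three leaves: single trifurcation
            children = sorted(self.adj[u], key=lambda c: self.labels[c])
            return "(" + ",".join(self.labels[c] for c in children) + ");"
        v = min(internal_nbrs, key=lambda w: self._min_leaf(w, u))
        left = self._render_rooted(u, v)
        right = self._render_rooted(v, u)
        return "(%s,%s);" % (left, right)

    def _render_rooted(self, node: int, excluded: int) -> str:
        if node in self.labels:
            return self.labels[node]
        children = sorted(
            (c for c in self.adj[node] if c != excluded),
            key=lambda c: self._min_leaf(c, node),
        )
        return "(" + ",".join(self._render(c, node) for c in children) + ")"

    @classmethod
    def from_newick(cls, text: str) -> "UnrootedTree":
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        t = cls()
        node_map: Dict[object, int] = {}
        for node in dt.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else None
            node_map[node] = t.new_node(label)
        for node in dt.preorder_node_iter():
            for child in node.child_nodes():
                t.add_edge(node_map[node], node_map[child])
        # suppress a degree-2 artificial root so the topology is unrooted
        root = node_map[dt.seed_node]
        if root not in t.labels and t.degree(root) == 2:
            a, b = sorted(t.adj[root])
            t.remove_edge(root, a)
            t.remove_edge(root, b)
            del t.adj[root]
            t.add_edge(a, b)
        labels = list(t.labels.values())
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in newick input")
        return t


def write_newick(tree: UnrootedTree, path) -> None:
    """Write ``tree`` in canonical newick form (deterministic child order)."""
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> UnrootedTree:
    with open(path) as fh:
        return UnrootedTree.from_newick(fh.read())
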