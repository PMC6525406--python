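"""Lightweight rooted-tree container shared by the phylogeny and migration modules.

Branch lengths live on the child node (length of the edge above it). Internal
nodes may carry bootstrap supports (0-100) and absolute ages in Myr. Newick
parsing is delegated to dendropy; serialization is done directly.
"""

from __future__ import annotations

import itertools
from typing import Callable, Iterator, Optional

import dendropy


class Node:
    __slots__ = ("label", "length", "children", "parent", "support", "age")

    def __init__(self, label: Optional[str] = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.support: Optional[float] = None
        self.age: Optional[float] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length:.4g}, n_children={len(self.children)})"


class Tree:
    """Rooted tree with unique tip labels."""

    def __init__(self, root: Node):
        self.root = root
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        def walk(node: Node) -> Iterator[Node]:
            for child in node.children:
                yield from walk(child)
            yield node

        return walk(self.root)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> Node:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labeled {label!r}")

    def internal_edges(self) -> list[Node]:
        """Child nodes of edges whose both ends are internal (NNI-eligible)."""
        return [
            n
            for n in self.postorder()
            if not n.is_leaf and n.parent is not None
        ]

    # -- structure ---------------------------------------------------------

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length)
            new.support = node.support
            new.age = node.age
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Tree(clone(self.root))

    def mrca(self, labels) -> Node:
        want = set(labels)
        best = None
        for node in self.postorder():
            below = {n.label for n in _subtree_leaves(node)}
            if want <= below and (best is None):
                best = node
        if best is None:
            raise KeyError(f"labels {sorted(want)} not all present")
        return best

    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node] = out[node.parent] + node.length
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted splits, each encoded as the tip side NOT containing the
        lexicographically smallest tip label (canonical form)."""
        all_tips = set(self.tip_labels())
        anchor = min(all_tips)
        splits: set[frozenset[str]] = set()
        for node in self.postorder():
            below = {n.label for n in _subtree_leaves(node)}
            if len(below) < 2 or len(all_tips - below) < 2:
                continue
            side = below if anchor not in below else all_tips - below
            splits.add(frozenset(side))
        return splits

    # -- serialization -----------------------------------------------------

    def to_newick(self, support: bool = False, digits: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.{digits}g}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = ""
            if support and node.support is not None:
                lab = f"{node.support:g}"
            elif node.label:
                lab = node.label
            return f"({inner}){lab}:{node.length:.{digits}g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        lab = self.root.label or ""
        if support and self.root.support is not None:
            lab = f"{self.root.support:g}"
        return f"({inner}){lab};"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")

        def convert(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label, dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dt.seed_node))


def _subtree_leaves(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def same_unrooted_topology(a: Tree, b: Tree) -> bool:
    if set(a.tip_labels()) != set(b.tip_labels()):
        return False
    return a.bipartitions() == b.bipartitions()
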