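"""Minimal phylogenetic tree container shared by inference, rooting and scoring.

The tree is a rooted data structure in memory; an *unrooted* tree is stored
with a trifurcating top node and ``rooted=False``.  Branch lengths are in
substitutions/site; integer bootstrap supports (0-100) may sit on internal
nodes (the support of the bipartition induced by the edge above the node).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


class TreeError(ValueError):
    pass


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0  # branch length to parent; ignored for the root
    support: Optional[int] = None
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = field(default=None, repr=False, compare=False)

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())


@dataclass
class Tree:
    root: Node
    rooted: bool = False

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> Node:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise TreeError(f"unknown tip {name!r}")

    # -- bipartitions -----------------------------------------------------

    def bipartitions(self) -> dict[frozenset[str], Node]:
        """Non-trivial bipartitions of the (implicitly unrooted) tree.

        Each internal edge (above ``node``) induces the split
        ``leaves(node) | rest``.  The returned key is the canonical side:
        the one *not* containing the alphabetically first leaf, so the same
        split hashes identically whichever way the tree happens to be
        oriented.  Trivial splits (single leaf / single complement) are
        omitted.
        """
        all_leaves = self.leaf_names()
        anchor = min(all_leaves)
        out: dict[frozenset[str], Node] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            if len(side) < 2 or len(all_leaves) - len(side) < 2:
                continue
            key = frozenset(all_leaves - side) if anchor in side else side
            out[key] = node
        return out

    def mrca(self, names) -> Node:
        """Most recent common ancestor of the named tips (rooted trees)."""
        names = set(names)
        if not names:
            raise TreeError("empty tip set")
        paths = []
        for name in names:
            leaf = self.find_leaf(name)
            path = []
            node = leaf
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(list(reversed(path)))
        prefix = paths[0]
        for path in paths[1:]:
            i = 0
            while i < min(len(prefix), len(path)) and prefix[i] is path[i]:
                i += 1
            prefix = prefix[:i]
        if not prefix:
            raise TreeError("tips share no ancestor")
        return prefix[-1]

    # -- serialization ----------------------------------------------------

    def to_newick(self, *, support_decimals: int = 0) -> str:
        for leaf in self.leaves():
            if not leaf.name:
                raise TreeError("cannot serialize a tree with an unnamed leaf")

        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if node.support is not None:
                    if support_decimals:
                        label = f"{node.support:.{support_decimals}f}"
                    else:
                        label = str(int(round(node.support)))
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.6f}"

        return fmt(self.root, True) + ";"

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            clone = Node(node.name, node.length, node.support)
            for child in node.children:
                clone.add(rec(child))
            return clone

        return Tree(rec(self.root), rooted=self.rooted)
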