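"""Phylogenetic tree structure, Newick I/O, bipartitions, RF and RFL metrics.

Branch lengths are expected substitutions per site.  A rooted tree has a
bifurcating root; an unrooted tree is represented with a trifurcating root
node.  Clock (ultrametric) trees additionally carry node heights, with tips
at height zero and each branch length equal to the parent/child height
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import dendropy


class NewickError(ValueError):
    """Malformed Newick input."""


class TreeNode:
    """Node with parent/child links, a branch length to its parent, and an
    optional height (clock mode)."""

    __slots__ = ("name", "children", "parent", "length", "height")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length
        self.height: float | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, len={self.length:g})"


class PhyloTree:
    """Tree rooted at ``root``; ``rooted`` distinguishes clock-style rooted
    trees from unrooted trees stored with a trifurcating root."""

    def __init__(self, root: TreeNode, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        names = [t.name for t in self.tips()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels")
        if any(n is None or n == "" for n in names):
            raise ValueError("unlabeled tip")
        for node in self.postorder():
            if node is not self.root and not (node.length >= 0.0 and node.length < float("inf")):
                raise ValueError(f"branch length must be finite and >= 0, got {node.length!r}")

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def find_tip(self, name: str) -> TreeNode:
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(name)

    # -- misc --------------------------------------------------------------

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            new.height = node.height
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root), self.rooted)

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        depths = {}
        for node in self.preorder():
            depths[id(node)] = (0.0 if node is self.root else depths[id(node.parent)] + node.length)
        tip_depths = [depths[id(t)] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) <= tol * max(1.0, max(tip_depths))

    def set_heights_from_lengths(self) -> None:
        """Derive node heights from branch lengths (tips forced to 0)."""
        depth = {id(self.root): 0.0}
        maxdepth = 0.0
        for node in self.preorder():
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + node.length
                maxdepth = max(maxdepth, depth[id(node)])
        for node in self.preorder():
            node.height = maxdepth - depth[id(node)]

    def set_lengths_from_heights(self) -> None:
        for node in self.preorder():
            if node is not self.root:
                node.length = node.parent.height - node.height
                if node.length < 0:
                    raise ValueError("negative branch implied by node heights")


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> PhyloTree:
    """Parse one Newick tree; missing branch lengths default to 0."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise NewickError(f"cannot parse Newick: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = TreeNode(label, dnode.edge.length if dnode.edge.length is not None else 0.0)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    if not root.children:
        raise NewickError("tree has no branches")
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def write_newick(tree: PhyloTree) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_tip:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node is tree.root:
            return body
        return f"{body}:{node.length:.12g}"

    return fmt(tree.root) + ";"


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# bipartitions and tree metrics


@dataclass(frozen=True)
class Bipartition:
    """One split of the taxon set induced by removing an edge.

    ``split`` is the smaller side (lexicographically smallest side on ties)
    so equality is well defined; ``length`` is the removed edge's length.
    """

    split: frozenset[str]
    length: float


def _split_lengths(tree: PhyloTree, include_trivial: bool) -> dict[frozenset, float]:
    """Canonical split -> branch length, after unrooting.

    The canonical form of a split is the side *not* containing the reference
    taxon (the lexicographically smallest tip name); a bifurcating root's two
    edges collapse to a single unrooted edge whose length is their sum.
    """
    taxa = frozenset(tree.tip_names())
    ref = min(taxa)
    below: dict[int, frozenset] = {}
    result: dict[frozenset, float] = {}
    root_children = tree.root.children
    merge_root = len(root_children) == 2
    for node in tree.postorder():
        if node.is_tip:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node is tree.root:
            continue
        side = below[id(node)]
        if merge_root and node.parent is tree.root:
            # the two root edges are one unrooted edge; record it once
            if node is root_children[1]:
                continue
            length = root_children[0].length + root_children[1].length
        else:
            length = node.length
        size = min(len(side), len(taxa) - len(side))
        if size == 0:
            continue
        if size == 1 and not include_trivial:
            continue
        canon = side if ref not in side else taxa - side
        result[canon] = result.get(canon, 0.0) + length
    return result


def bipartitions(tree: PhyloTree, include_trivial: bool = False) -> set[Bipartition]:
    """Bipartition set of the (unrooted) tree.

    Non-trivial splits only by default; with ``include_trivial`` the pendant
    edges are included as singleton splits.
    """
    taxa = frozenset(tree.tip_names())

    def smaller(side: frozenset) -> frozenset:
        other = taxa - side
        if len(side) != len(other):
            return side if len(side) < len(other) else other
        return side if tuple(sorted(side)) < tuple(sorted(other)) else other

    return {
        Bipartition(smaller(side), length)
        for side, length in _split_lengths(tree, include_trivial).items()
    }


def _check_same_taxa(t1: PhyloTree, t2: PhyloTree) -> None:
    s1, s2 = set(t1.tip_names()), set(t2.tip_names())
    if s1 != s2:
        raise ValueError(
            f"trees have different taxon sets (only in first: {sorted(s1 - s2)}, "
            f"only in second: {sorted(s2 - s1)})"
        )


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> int:
    """Robinson-Foulds symmetric difference of non-trivial bipartitions.

    Both trees are unrooted before comparison; the result is an even integer
    bounded by ``2 * (n - 3)`` for fully resolved trees.
    """
    _check_same_taxa(t1, t2)
    b1 = set(_split_lengths(t1, include_trivial=False))
    b2 = set(_split_lengths(t2, include_trivial=False))
    return len(b1 ^ b2)


def rfl_distance(t1: PhyloTree, t2: PhyloTree) -> float:
    """Branch-length Robinson-Foulds distance.

    Sum over the union of bipartitions (trivial and non-trivial) of the
    absolute branch-length difference, a split absent from one tree counting
    as length zero there.  Trees are unrooted first.
    """
    _check_same_taxa(t1, t2)
    m1 = _split_lengths(t1, include_trivial=True)
    m2 = _split_lengths(t2, include_trivial=True)
    return sum(abs(m1.get(k, 0.0) - m2.get(k, 0.0)) for k in set(m1) | set(m2))


def total_length(tree: PhyloTree) -> float:
    """Sum of all branch lengths."""
    return sum(n.length for n in tree.postorder() if n is not tree.root)
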