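"""Unrooted phylogenetic trees: newick IO, splits, RF, consensus, NNI.

Trees are stored in the usual rooted representation of an unrooted
topology: the root is an internal node of degree three (a binary
unrooted tree on n taxa then has 2n-3 edges), every other internal
node has two children, and edge lengths are expected substitutions per
site.  Support values (bootstrap percentages) attach to internal
nodes, i.e. to the edge above them.

Newick parsing is delegated to dendropy; writing is direct.
"""

from __future__ import annotations

from typing import Iterable, Optional

import dendropy

__all__ = ["Node", "Tree", "rf_distance", "majority_consensus", "enumerate_topologies"]


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list[Node] = []
        self.parent: Optional[Node] = None
        self.support: Optional[float] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A phylogenetic tree over named leaves."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction ------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)

        def convert(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            node = Node(name=label, length=dn.edge.length or 0.0)
            for ch in dn.child_nodes():
                node.add(convert(ch))
            if node.children and node.name is not None:
                try:  # internal labels are supports
                    node.support = float(node.name)
                    node.name = None
                except ValueError:
                    pass
            return node

        return cls(convert(dt.seed_node))

    def to_newick(self, include_support: bool = False, precision: int = 6) -> str:
        def fmt(node: Node, top: bool) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                inner = ",".join(fmt(c, False) for c in node.children)
                label = ""
                if include_support and node.support is not None and not top:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if top:
                return body
            return f"{body}:{node.length:.{precision}f}"

        return fmt(self.root, True) + ";"

    def copy(self) -> "Tree":
        def dup(n: Node) -> Node:
            m = Node(n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(dup(c))
            return m

        return Tree(dup(self.root))

    # -- traversal ---------------------------------------------------
    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(sorted(n.name for n in self.leaves()))

    def n_edges(self) -> int:
        return sum(1 for n in self.postorder() if n is not self.root)

    # -- unrooted semantics ------------------------------------------
    def suppress_unifurcations(self) -> None:
        for node in self.postorder():
            if node is self.root:
                continue
            if len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
        while len(self.root.children) == 1:
            old = self.root
            self.root = old.children[0]
            self.root.parent = None
            self.root.length = 0.0

    def unroot(self) -> None:
        """Ensure the root has three children (unrooted binary shape)."""
        self.suppress_unifurcations()
        while len(self.root.children) == 2:
            a, b = self.root.children
            merge = b if not b.is_leaf else a
            keep = a if merge is b else b
            if merge.is_leaf:  # two-taxon tree cannot be unrooted
                return
            keep.length += merge.length
            self.root.children = [keep] + merge.children
            for c in merge.children:
                c.parent = self.root
            keep.parent = self.root

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each as the side without the first taxon."""
        all_taxa = frozenset(self.taxa)
        ref = min(all_taxa)
        out: set[frozenset] = set()
        leafsets: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                leafsets[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(leafsets[id(c)] for c in node.children))
                leafsets[id(node)] = s
                if node is self.root:
                    continue
                side = all_taxa - s if ref in s else s
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(side)
        return out

    def internal_edges(self) -> list[Node]:
        """Internal (non-root, non-leaf) nodes == internal edges above them."""
        return [n for n in self.postorder() if n is not self.root and not n.is_leaf]


def path_distance_matrix(tree: Tree) -> tuple[list[str], "object"]:
    """Leaf-to-leaf patristic distances (additive on the tree's lengths)."""
    import numpy as np

    leaves = sorted(tree.leaves(), key=lambda n: n.name)
    names = [n.name for n in leaves]
    # distance from every node up to the root, then combine via LCA
    depth = {}
    parent = {}
    for node in tree.postorder():
        parent[id(node)] = node.parent
    for node in reversed(tree.postorder()):
        if node is tree.root:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(node.parent)] + node.length

    def ancestors(n):
        out = []
        while n is not None:
            out.append(id(n))
            n = parent[id(n)]
        return out

    anc = {id(n): ancestors(n) for n in leaves}
    D = np.zeros((len(leaves), len(leaves)))
    for i, a in enumerate(leaves):
        seta = set(anc[id(a)])
        for j in range(i + 1, len(leaves)):
            b = leaves[j]
            lca = next(x for x in anc[id(b)] if x in seta)
            D[i, j] = D[j, i] = depth[id(a)] + depth[id(b)] - 2 * depth[lca]
    return names, D


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds symmetric difference between split sets."""
    if t1.taxa != t2.taxa:
        raise ValueError("trees are over different taxon sets")
    return len(t1.splits() ^ t2.splits())


def nni_neighbors(tree: Tree, with_focal: bool = False):
    """All trees one nearest-neighbor interchange away.

    For each internal edge (parent u, child v) the subtrees X, Y under
    v are swapped in turn with v's sibling subtree under u, giving the
    two alternative resolutions around that edge.  With ``with_focal``
    each neighbor is returned as (tree, focal node) where the focal
    node subtends the rearranged edge in the new tree.
    """
    base = tree.copy()
    neighbors = []
    nodes = base.postorder()
    index = {id(n): i for i, n in enumerate(nodes)}
    for v in base.internal_edges():
        for which in (0, 1):
            t2 = base.copy()
            nodes2 = t2.postorder()
            v2 = nodes2[index[id(v)]]
            u2 = v2.parent
            sibs = [c for c in u2.children if c is not v2]
            if not sibs:
                continue
            s2 = sibs[0]
            x2 = v2.children[which]
            ui = u2.children.index(s2)
            vi = v2.children.index(x2)
            u2.children[ui], v2.children[vi] = x2, s2
            x2.parent, s2.parent = u2, v2
            neighbors.append((t2, v2) if with_focal else t2)
    return neighbors


def majority_consensus(trees: list[Tree], threshold: float = 0.5) -> Tree:
    """Majority-rule consensus with percentage supports on internal edges.

    Splits occurring in more than ``threshold`` of the input trees are
    retained; at threshold 0.5 they are mutually compatible and define
    a unique (possibly multifurcating) tree.
    """
    if not trees:
        raise ValueError("no input trees")
    taxa = trees[0].taxa
    for t in trees[1:]:
        if t.taxa != taxa:
            raise ValueError("trees are over different taxon sets")
    counts: dict[frozenset, int] = {}
    for t in trees:
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    n = len(trees)
    ref = min(taxa)
    # clades rooted at the reference taxon: the split side without ref
    kept = [(s, c) for s, c in counts.items() if c / n > threshold]
    kept.sort(key=lambda item: (-len(item[0]), sorted(item[0])))
    root = Node()
    leaf_nodes = {}
    for name in taxa:
        leaf_nodes[name] = root.add(Node(name=name, length=1.0))
    for clade, count in kept:
        # deepest node whose children cover the clade
        node = root
        while True:
            cover = [c for c in node.children if _leafset(c) <= clade]
            covered = frozenset().union(*(_leafset(c) for c in cover)) if cover else frozenset()
            if covered == clade:
                new = Node(length=1.0)
                new.support = 100.0 * count / n
                for c in cover:
                    node.children.remove(c)
                    new.add(c)
                node.add(new)
                break
            nxt = [c for c in node.children if clade <= _leafset(c)]
            if not nxt:
                break  # incompatible (only possible below 0.5 thresholds)
            node = nxt[0]
    return Tree(root)


def _leafset(node: Node) -> frozenset:
    if node.is_leaf:
        return frozenset([node.name])
    return frozenset().union(*(_leafset(c) for c in node.children))


def enumerate_topologies(taxa: Iterable[str]) -> list[Tree]:
    """All distinct unrooted binary topologies over the taxa.

    (2n-5)!! trees; intended for exhaustive checks at small n.
    """
    taxa = list(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    root = Node()
    for name in taxa[:3]:
        root.add(Node(name=name, length=1.0))
    trees = [Tree(root)]
    for name in taxa[3:]:
        grown: list[Tree] = []
        for t in trees:
            n_nodes = len(t.postorder())
            for k in range(n_nodes):
                t2 = t.copy()
                target = t2.postorder()[k]
                if target is t2.root:
                    continue
                parent = target.parent
                idx = parent.children.index(target)
                mid = Node(length=1.0)
                parent.children[idx] = mid
                mid.parent = parent
                mid.add(target)
                mid.add(Node(name=name, length=1.0))
                grown.append(t2)
        trees = grown
    return trees
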