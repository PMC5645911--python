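"""Light-weight phylogenetic tree for likelihood computation and topology
search.

Unrooted trees are stored rooted at an internal node with a basal
trifurcation (the standard convention); under reversible models the
likelihood does not depend on that choice. Node ids are stable across
copies, so edges can be addressed while trees are rearranged.
"""
from __future__ import annotations

import itertools

import numpy as np


class PhyloNode:
    __slots__ = ("id", "name", "length", "children", "parent", "support")

    def __init__(self, id: int, name: str | None = None, length: float = 0.0):
        self.id = id
        self.name = name
        self.length = length
        self.children: list["PhyloNode"] = []
        self.parent: "PhyloNode" | None = None
        self.support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "PhyloNode") -> None:
        child.parent = self
        self.children.append(child)


class PhyloTree:
    def __init__(self, root: PhyloNode):
        self.root = root
        self._reindex()

    def _reindex(self) -> None:
        self._by_id = {n.id: n for n in self.postorder()}

    def node(self, node_id: int) -> PhyloNode:
        return self._by_id[node_id]

    def postorder(self) -> list[PhyloNode]:
        out: list[PhyloNode] = []

        def walk(n: PhyloNode) -> None:
            for c in n.children:
                walk(c)
            out.append(n)

        walk(self.root)
        return out

    def tips(self) -> list[PhyloNode]:
        return [n for n in self.postorder() if n.is_leaf()]

    def tip_labels(self) -> list[str]:
        return [n.name for n in self.tips()]

    def n_tips(self) -> int:
        return len(self.tips())

    def branch_nodes(self) -> list[PhyloNode]:
        """All non-root nodes; each carries the branch to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[int]:
        """Ids of internal nodes whose parent edge is an internal branch."""
        return [n.id for n in self.postorder()
                if n.parent is not None and not n.is_leaf()]

    def copy(self) -> "PhyloTree":
        def dup(n: PhyloNode) -> PhyloNode:
            m = PhyloNode(n.id, n.name, n.length)
            m.support = n.support
            for c in n.children:
                m.add(dup(c))
            return m

        return PhyloTree(dup(self.root))

    # --- newick ---------------------------------------------------------

    def to_newick(self, with_support: bool = False,
                  with_lengths: bool = True) -> str:
        def fmt(n: PhyloNode) -> str:
            if n.is_leaf():
                s = n.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if with_support and n.support is not None:
                    s += f"{n.support:g}"
                elif n.name:
                    s += n.name
            if with_lengths and n.parent is not None:
                s += f":{n.length:.6g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, unroot: bool = True) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        counter = itertools.count()

        def conv(dnode) -> PhyloNode:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            n = PhyloNode(next(counter), name,
                          dnode.edge.length if dnode.edge.length else 0.0)
            for c in dnode.child_nodes():
                n.add(conv(c))
            return n

        tree = cls(conv(dtree.seed_node))
        if unroot and tree.n_tips() >= 3:
            tree.unroot()
        return tree

    def unroot(self) -> None:
        """Collapse a bifurcating root into a basal trifurcation."""
        while len(self.root.children) == 2:
            a, b = self.root.children
            target = a if not a.is_leaf() else b if not b.is_leaf() else None
            if target is None:
                break  # two-taxon tree
            other = b if target is a else a
            other.length += target.length
            self.root.children = [c for c in self.root.children if c is not target]
            for c in target.children:
                self.root.children.append(c)
                c.parent = self.root
            target.children = []
        self._reindex()

    # --- topology -------------------------------------------------------

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each as the frozenset of tip labels on
        the child side; canonicalized by taking the lexicographically smaller
        side so unrooted topologies compare equal."""
        all_tips = frozenset(self.tip_labels())
        out = set()
        for n in self.postorder():
            if n.parent is None or n.is_leaf():
                continue
            side = frozenset(t.name for t in _tips_under(n))
            comp = all_tips - side
            if len(side) < 2 or len(comp) < 2:
                continue
            out.add(min(side, comp, key=lambda s: sorted(s)))
        return frozenset(out)

    def same_topology(self, other: "PhyloTree") -> bool:
        return (set(self.tip_labels()) == set(other.tip_labels())
                and self.splits() == other.splits())

    def clade_node(self, taxon_set: set[str]) -> PhyloNode | None:
        """Node whose parent branch induces the bipartition separating
        ``taxon_set`` from the rest, if that bipartition exists."""
        all_tips = set(self.tip_labels())
        unknown = set(taxon_set) - all_tips
        if unknown:
            raise KeyError(f"unknown taxa: {sorted(unknown)}")
        want = frozenset(taxon_set)
        comp = frozenset(all_tips - want)
        for n in self.postorder():
            if n.parent is None:
                continue
            side = frozenset(t.name for t in _tips_under(n))
            if side == want or side == comp:
                return n
        return None


def _tips_under(node: PhyloNode) -> list[PhyloNode]:
    if node.is_leaf():
        return [node]
    out = []
    for c in node.children:
        out.extend(_tips_under(c))
    return out


def star_tree(labels: list[str], length: float = 0.1) -> PhyloTree:
    root = PhyloNode(0)
    for i, lab in enumerate(labels, start=1):
        root.add(PhyloNode(i, lab, length))
    return PhyloTree(root)


def _fresh_ids(tree: PhyloTree) -> None:
    for i, n in enumerate(tree.postorder()):
        n.id = i
    tree._reindex()


def _attach_on_edge(tree: PhyloTree, edge_child: PhyloNode, new_leaf: PhyloNode,
                    length: float = 0.1) -> None:
    """Split the branch above ``edge_child`` and hang ``new_leaf`` there."""
    parent = edge_child.parent
    mid = PhyloNode(-1, None, edge_child.length / 2)
    edge_child.length /= 2
    idx = parent.children.index(edge_child)
    parent.children[idx] = mid
    mid.parent = parent
    mid.add(edge_child)
    mid.add(new_leaf)


def enumerate_topologies(labels: list[str], length: float = 0.1
                         ) -> list[PhyloTree]:
    """All unrooted fully-resolved topologies on the labels, by sequential
    insertion on every edge ((2n-5)!! trees: 3 for 4 taxa, 15 for 5)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    trees = [star_tree(labels[:3], length)]
    for lab in labels[3:]:
        nxt = []
        for t in trees:
            for edge_child in t.branch_nodes():
                t2 = t.copy()
                target = t2.node(edge_child.id)
                _attach_on_edge(t2, target, PhyloNode(-2, lab, length), length)
                _fresh_ids(t2)
                nxt.append(t2)
        trees = nxt
    return trees


def random_topology(labels: list[str], rng: np.random.Generator,
                    length: float = 0.1) -> PhyloTree:
    """Uniform random unrooted topology by random sequential insertion."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    order = list(rng.permutation(labels))
    tree = star_tree(order[:3], length)
    for lab in order[3:]:
        branches = tree.branch_nodes()
        edge_child = branches[int(rng.integers(len(branches)))]
        _attach_on_edge(tree, edge_child, PhyloNode(-2, lab, length), length)
        _fresh_ids(tree)
    return tree


def resolve_polytomies(tree: PhyloTree, rng: np.random.Generator,
                       length: float = 1e-6) -> PhyloTree:
    """Randomly resolve multifurcations (root keeps its trifurcation)."""
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in t.postorder():
            limit = 3 if n.parent is None else 2
            if len(n.children) > limit:
                picks = rng.choice(len(n.children), size=2, replace=False)
                a, b = (n.children[int(i)] for i in sorted(picks))
                joint = PhyloNode(-3, None, length)
                n.children = [c for c in n.children if c is not a and c is not b]
                n.add(joint)
                joint.add(a)
                joint.add(b)
                changed = True
                break
    _fresh_ids(t)
    return t


def nni_neighbors(tree: PhyloTree, edge_child_id: int) -> list[PhyloTree]:
    """The two nearest-neighbor-interchange rearrangements around the
    internal branch above node ``edge_child_id``."""
    c0 = tree.node(edge_child_id)
    if c0.is_leaf() or c0.parent is None:
        raise ValueError("NNI requires an internal, non-root edge child")
    if len(c0.children) != 2:
        raise ValueError("NNI requires binary internal nodes")
    p0 = c0.parent
    others = [ch for ch in p0.children if ch is not c0]
    if not others:
        raise ValueError("degenerate edge")
    b_id = others[-1].id
    out = []
    for swap_idx in (0, 1):
        t2 = tree.copy()
        c = t2.node(edge_child_id)
        p = c.parent
        b = t2.node(b_id)
        x = c.children[swap_idx]
        pi = p.children.index(b)
        ci = c.children.index(x)
        p.children[pi], c.children[ci] = x, b
        x.parent, b.parent = p, c
        out.append(t2)
    return out
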