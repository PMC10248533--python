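"""Phylogeny container plus Newick I/O and topology manipulation.

Trees are rooted node structures; an unrooted tree is represented with a
trifurcating virtual root (``rooted=False``). Branch lengths live on the
child node of each edge; bootstrap supports (0..100) live on the upper
(child) node of internal edges, i.e. the node printed just after ``)`` in
Newick. Parsing is delegated to dendropy; the canonical writer is local so
the round-trip contract (topology, lengths to 6 decimals, supports) is
under package control.
"""
from __future__ import annotations

from typing import Dict, FrozenSet, Iterable, List, Optional, Set

import dendropy


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None,
                 support: Optional[float] = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: List["Node"] = []
        self.parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class Phylogeny:
    """A tree with branch lengths, internal supports and a rooted flag."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        names = self.leaf_names()
        if len(names) != len(set(names)):
            raise ValueError("duplicate leaf labels")

    # ------------------------------------------------------------------ walks
    def postorder(self) -> Iterable[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def preorder(self) -> Iterable[Node]:
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def leaves(self) -> List[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(f"leaf {name!r} not in tree")

    def edges(self) -> List[Node]:
        """Every non-root node identifies the edge to its parent."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> List[Node]:
        return [n for n in self.edges() if not n.is_leaf]

    def copy(self) -> "Phylogeny":
        def clone(n: Node) -> Node:
            c = Node(n.name, n.length, n.support)
            for ch in n.children:
                c.add(clone(ch))
            return c
        return Phylogeny(clone(self.root), self.rooted)

    # ------------------------------------------------------------- summaries
    def leaf_set(self, node: Node) -> FrozenSet[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def mrca(self, names: Iterable[str]) -> Node:
        """Most recent common ancestor of the named leaves (rooted sense)."""
        want = set(names)
        missing = want - set(self.leaf_names())
        if missing:
            raise KeyError(f"leaves not in tree: {sorted(missing)}")
        counts: Dict[int, int] = {}
        node_by_id: Dict[int, Node] = {}
        for leaf in self.leaves():
            if leaf.name in want:
                n = leaf
                while n is not None:
                    counts[id(n)] = counts.get(id(n), 0) + 1
                    node_by_id[id(n)] = n
                    n = n.parent
        # deepest node covering all wanted leaves
        best = self.root
        best_depth = -1
        for nid, c in counts.items():
            if c == len(want):
                n = node_by_id[nid]
                d = 0
                p = n
                while p.parent is not None:
                    d += 1
                    p = p.parent
                if d > best_depth:
                    best, best_depth = n, d
        return best

    def bipartitions(self) -> Set[FrozenSet[str]]:
        """Unrooted bipartitions induced by internal edges, each encoded as
        the side NOT containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: Set[FrozenSet[str]] = set()
        for n in self.internal_edges():
            side = self.leaf_set(n)
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:   # both sides >= 2 leaves
                out.add(side)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        na, nb = self.find_leaf(a), self.find_leaf(b)
        anc_a = {}
        d, n = 0.0, na
        while n is not None:
            anc_a[id(n)] = d
            d += n.length or 0.0
            n = n.parent
        d, n = 0.0, nb
        while n is not None:
            if id(n) in anc_a:
                return d + anc_a[id(n)]
            d += n.length or 0.0
            n = n.parent
        raise RuntimeError("disconnected tree")  # pragma: no cover

    # -------------------------------------------------------------- editing
    def suppress_unifurcations(self) -> None:
        """Remove degree-2 internal nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for n in list(self.postorder()):
                if n.parent is not None and len(n.children) == 1:
                    child = n.children[0]
                    child.length = (child.length or 0.0) + (n.length or 0.0)
                    if child.support is None:
                        child.support = n.support
                    p = n.parent
                    p.children[p.children.index(n)] = child
                    child.parent = p
                    changed = True
        # root unifurcation
        while len(self.root.children) == 1 and not self.root.is_leaf:
            child = self.root.children[0]
            child.parent = None
            child.length = None
            self.root = child


def read_newick(text: str) -> Phylogeny:
    """Parse Newick into a Phylogeny.

    Internal-node labels that parse as numbers in [0,100] are taken as
    bootstrap supports; other labels are kept as internal node names.
    A tree whose root has three or more children is flagged unrooted.
    """
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc

    def convert(dn) -> Node:
        name = None
        if dn.taxon is not None:
            name = dn.taxon.label
        support = None
        if dn.label is not None:
            try:
                val = float(dn.label)
                if 0 <= val <= 100 and not dn.is_leaf():
                    support = val
                else:
                    name = dn.label
            except ValueError:
                name = dn.label
        node = Node(name=name, length=dn.edge.length, support=support)
        for c in dn.child_nodes():
            node.add(convert(c))
        return node

    root = convert(dt.seed_node)
    if not root.children:
        raise ValueError("Newick parse error: no tree structure")
    tree = Phylogeny(root, rooted=len(root.children) <= 2)
    return tree


def _fmt_length(x: float) -> str:
    s = f"{x:.6f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _fmt_support(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def write_newick(tree: Phylogeny) -> str:
    def fmt(n: Node) -> str:
        if n.is_leaf:
            s = n.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n.support is not None:
                s += _fmt_support(n.support)
            elif n.name:
                s += n.name
        if n.length is not None and n.parent is not None:
            s += f":{_fmt_length(n.length)}"
        return s

    return fmt(tree.root) + ";"


# ----------------------------------------------------------------- rooting
def unroot(tree: Phylogeny) -> Phylogeny:
    """Return a copy represented with a trifurcating virtual root."""
    t = tree.copy()
    if len(t.root.children) == 2:
        a, b = t.root.children
        # merge the two root edges onto one child, promote the other side
        keep, move = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:  # two-leaf tree cannot be unrooted further
            t.rooted = False
            return t
        move.length = (move.length or 0.0) + (keep.length or 0.0)
        move.support = move.support if move.support is not None else keep.support
        new_root = Node()
        for c in keep.children:
            new_root.add(c)
        new_root.add(move)
        t.root = new_root
        new_root.parent = None
    t.rooted = False
    return t


def root_at_edge(tree: Phylogeny, child: Node, lower_fraction: float = 0.5) -> Phylogeny:
    """Root on the edge above ``child``, placing the new root so the child
    keeps ``lower_fraction`` of the edge length. Operates in place on the
    given (copied) structure and returns a Phylogeny."""
    t_len = child.length if child.length is not None else 0.0
    old_parent = child.parent
    if old_parent is None:
        raise ValueError("cannot root at the root edge")
    new_root = Node()
    old_parent.children.remove(child)
    new_root.add(child)
    child.length = t_len * lower_fraction

    # reverse parent pointers from old_parent up to the old root
    prev = new_root
    prev_len = t_len * (1.0 - lower_fraction)
    prev_support = child.support
    node = old_parent
    while node is not None:
        nxt = node.parent
        nxt_len = node.length
        nxt_support = node.support
        node.parent = None
        if node in getattr(nxt, "children", []):
            nxt.children.remove(node)
        prev.add(node)
        node.length = prev_len
        node.support = prev_support
        prev, prev_len, prev_support = node, nxt_len, nxt_support
        node = nxt

    out = Phylogeny(new_root, rooted=True)
    out.suppress_unifurcations()
    return out


def root_at_mrca(tree: Phylogeny, taxon_a: str, taxon_b: str) -> Phylogeny:
    """Root on the edge immediately ancestral to the MRCA clade of the two
    anchor taxa on the unrooted tree, splitting that edge at its midpoint.

    On an unrooted tree the MRCA clade of {A, B} is the smallest edge-side
    containing both anchors (e.g. unrooted ((A,B),(C,D)) rooted at
    mrca(A,B) yields {A,B} as one child clade); ties break on the
    lexicographically smallest side. Idempotent, and path lengths between
    leaves are preserved.
    """
    u = unroot(tree)
    for name in (taxon_a, taxon_b):
        u.find_leaf(name)  # raises KeyError if absent
    all_leaves = frozenset(u.leaf_names())
    best = None      # (side size, sorted side, edge node, side_is_subtree)
    for n in u.edges():
        side = u.leaf_set(n)
        other = all_leaves - side
        for cand, is_sub in ((side, True), (other, False)):
            if taxon_a in cand and taxon_b in cand:
                key = (len(cand), tuple(sorted(cand)))
                if best is None or key < best[0]:
                    best = (key, n, is_sub)
    _, node, _ = best   # the edge is the same whichever side holds the anchors
    return root_at_edge(u, node)


def collapse_low_support(tree: Phylogeny, threshold: float = 70.0) -> Phylogeny:
    """Contract every internal edge whose support is below ``threshold``
    (strictly), producing a multifurcating tree. Edges with support equal
    to the threshold are retained."""
    t = tree.copy()
    changed = True
    while changed:
        changed = False
        for n in list(t.postorder()):
            if (n.parent is not None and not n.is_leaf
                    and n.support is not None and n.support < threshold):
                p = n.parent
                idx = p.children.index(n)
                p.children.pop(idx)
                for i, c in enumerate(n.children):
                    c.parent = p
                    p.children.insert(idx + i, c)
                changed = True
    return t


def test_monophyly(tree: Phylogeny, leaf_names: Iterable[str]) -> bool:
    """True iff some clade of the rooted tree has exactly this leaf set."""
    want = set(leaf_names)
    have = set(tree.leaf_names())
    unknown = want - have
    if unknown:
        raise KeyError(f"leaves not in tree: {sorted(unknown)}")
    node = tree.mrca(want)
    return tree.leaf_set(node) == frozenset(want)
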