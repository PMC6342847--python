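"""Rooted phylogenetic trees, rooted triples, and the BUILD algorithm.

A *rooted triple* ``ab|c`` is the rooted binary tree on three leaves in
which a and b form the cherry and c is adjacent to the root.  A rooted
phylogenetic tree T *displays* ab|c when the most recent common
ancestor of {a, b} lies strictly below that of {a, b, c}; a set R of
triples is *compatible* when one tree displays them all.

Compatibility is decided by the BUILD algorithm of Aho et al.: the
current taxon set is partitioned by the connected components of the
cluster graph [R, S] (vertices S, edge {a, b} for each triple ab|c with
all three leaves in S); a single component of size >= 2 at any level
means the triples are incompatible, otherwise recursion over the
components yields the canonical supertree.  The same graph underlies
the Bryant-Steel criterion: R is compatible iff [R, S] is disconnected
for every S with |S| >= 2.

The module also provides exhaustive enumeration of rooted binary tree
shapes (the (2n-3)!! oracle used throughout the test suite), exact
counts of displaying trees, the closed-form count for leaf-disjoint
triples, and the recursive construction of n-2 triples that pin down a
binary tree uniquely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Iterator, Sequence

import networkx as nx

from .set_systems import CapacityError, SetSystemError, validate_label

__all__ = [
    "RootedTriple",
    "TreeNode",
    "RootedTree",
    "TripleSet",
    "displays_triple",
    "induced_triples",
    "displays_tree",
    "cluster_graph",
    "is_compatible",
    "refine_binary",
    "enumerate_rooted_binary_trees",
    "count_displaying_trees",
    "disjoint_display_count",
    "unique_defining_triples",
    "double_factorial",
    "ENUMERATION_CAP",
]

# Exhaustive tree enumeration is refused above this leaf count unless
# explicitly overridden ((2*10-3)!! is already ~34 million shapes).
ENUMERATION_CAP = 9


# ---------------------------------------------------------------------------
# Rooted triples
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True, init=False)
class RootedTriple:
    """The rooted binary tree ab|c on three leaves (a, b the cherry)."""

    cherry: tuple
    outgroup: str

    def __init__(self, a: str, b: str, c: str) -> None:
        a, b, c = validate_label(a), validate_label(b), validate_label(c)
        if len({a, b, c}) != 3:
            raise SetSystemError(f"triple labels must be distinct: {a!r},{b!r},{c!r}")
        lo, hi = sorted((a, b))
        object.__setattr__(self, "cherry", (lo, hi))
        object.__setattr__(self, "outgroup", c)

    @property
    def labels(self) -> frozenset:
        return frozenset((*self.cherry, self.outgroup))

    def as_tuple(self) -> tuple:
        return (*self.cherry, self.outgroup)

    def __str__(self) -> str:
        return f"{self.cherry[0]},{self.cherry[1]}|{self.outgroup}"

    @classmethod
    def parse(cls, text: str) -> "RootedTriple":
        """Parse 'a,b|c'; 'ab|c' is accepted for single-character labels."""
        text = text.strip()
        if "|" not in text:
            raise SetSystemError(f"malformed triple (no '|'): {text!r}")
        left, _, c = text.partition("|")
        if "," in left:
            a, _, b = left.partition(",")
        elif len(left) == 2:
            a, b = left[0], left[1]
        else:
            raise SetSystemError(f"malformed triple cherry: {left!r}")
        return cls(a.strip(), b.strip(), c.strip())


class TripleSet(frozenset):
    """A finite set of rooted triples (R); supports L(R) and ||R||."""

    def __new__(cls, triples: Iterable[RootedTriple] = ()):  # noqa: D102
        items = []
        for t in triples:
            if isinstance(t, str):
                t = RootedTriple.parse(t)
            if not isinstance(t, RootedTriple):
                raise SetSystemError(f"not a rooted triple: {t!r}")
            items.append(t)
        return super().__new__(cls, items)

    @property
    def leaves(self) -> frozenset:
        """L(R): union of the triples' leaf sets."""
        out: set = set()
        for t in self:
            out |= t.labels
        return frozenset(out)

    @property
    def support(self) -> frozenset:
        """||R||: the set of 3-element leaf sets of the triples."""
        return frozenset(t.labels for t in self)


# ---------------------------------------------------------------------------
# Rooted trees
# ---------------------------------------------------------------------------

class TreeNode:
    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None) -> None:
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class RootedTree:
    """A rooted phylogenetic tree: leaves labelled, interior out-degree >= 2.

    Trees compare equal when they have the same leaf set and the same
    set of clusters (leaf sets below each vertex), the standard
    identity for labelled rooted topologies.
    """

    def __init__(self, root: TreeNode) -> None:
        self.root = root
        self._index()

    def _index(self) -> None:
        self._leaf_node: dict[str, TreeNode] = {}
        for node in self.preorder():
            if node.is_leaf:
                if node.label is None:
                    raise SetSystemError("leaf without a label")
                if node.label in self._leaf_node:
                    raise SetSystemError(f"duplicate leaf label: {node.label!r}")
                self._leaf_node[node.label] = node
            elif len(node.children) < 2:
                raise SetSystemError("interior vertex with out-degree < 2")

    @classmethod
    def from_nested(cls, nested) -> "RootedTree":
        """Build from nested tuples/lists of labels, e.g. (('a','b'),'c')."""

        def mk(item) -> TreeNode:
            if isinstance(item, str):
                return TreeNode(validate_label(item))
            node = TreeNode()
            for sub in item:
                node.add(mk(sub))
            return node

        return cls(mk(nested))

    # -- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(self._leaf_node)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_node)

    @property
    def is_binary(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.preorder())

    @property
    def is_caterpillar(self) -> bool:
        """Rooted caterpillar: binary with at most one cherry."""
        return self.is_binary and len(self.cherries()) <= 1

    def cherries(self) -> list[frozenset]:
        out = []
        for node in self.preorder():
            kids = node.children
            if len(kids) == 2 and all(k.is_leaf for k in kids):
                out.append(frozenset(k.label for k in kids))
        return out

    def node_leafset(self) -> dict:
        """Map each node to the frozenset of leaf labels below it."""
        below: dict[TreeNode, frozenset] = {}
        for node in reversed(list(self.preorder())):
            if node.is_leaf:
                below[node] = frozenset((node.label,))
            else:
                acc: set = set()
                for k in node.children:
                    acc |= below[k]
                below[node] = frozenset(acc)
        return below

    def clusters(self) -> frozenset:
        return frozenset(self.node_leafset().values())

    def lca(self, labels: Iterable[str]) -> TreeNode:
        """Lowest common ancestor of the given leaf labels."""
        labels = list(labels)
        try:
            nodes = [self._leaf_node[x] for x in labels]
        except KeyError as e:
            raise SetSystemError(f"label {e.args[0]!r} is not a leaf of this tree")
        depth: dict[TreeNode, int] = {}

        def d(n: TreeNode) -> int:
            if n not in depth:
                depth[n] = 0 if n.parent is None else d(n.parent) + 1
            return depth[n]

        cur = nodes[0]
        for other in nodes[1:]:
            a, b = cur, other
            while d(a) > d(b):
                a = a.parent
            while d(b) > d(a):
                b = b.parent
            while a is not b:
                a, b = a.parent, b.parent
            cur = a
        return cur

    def prune_leaf(self, label: str) -> "RootedTree":
        """New tree with *label* removed and degree-2 vertices suppressed."""
        if label not in self._leaf_node:
            raise SetSystemError(f"label {label!r} is not a leaf of this tree")
        if self.n_leaves <= 2:
            raise SetSystemError("cannot prune a tree down below two leaves")

        def rebuild(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return None if node.label == label else TreeNode(node.label)
            kids = [k for k in (rebuild(c) for c in node.children) if k is not None]
            if len(kids) == 1:
                return kids[0]
            new = TreeNode()
            for k in kids:
                new.add(k)
            return new

        root = rebuild(self.root)
        assert root is not None
        return RootedTree(root)

    def copy(self) -> "RootedTree":
        return RootedTree.from_nested(self.to_nested())

    def to_nested(self):
        def conv(node: TreeNode):
            if node.is_leaf:
                return node.label
            return tuple(conv(k) for k in node.children)

        return conv(self.root)

    def to_newick(self) -> str:
        """Canonical Newick: children ordered by smallest descendant leaf."""
        below = self.node_leafset()

        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            kids = sorted(node.children, key=lambda k: min(below[k]))
            return "(" + ",".join(fmt(k) for k in kids) + ")"

        return fmt(self.root) + ";"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RootedTree):
            return NotImplemented
        return (
            self.leaf_labels == other.leaf_labels
            and self.clusters() == other.clusters()
        )

    def __hash__(self) -> int:
        return hash((self.leaf_labels, self.clusters()))

    def __repr__(self) -> str:
        return f"RootedTree({self.to_newick()!r})"


# ---------------------------------------------------------------------------
# Display relations
# ---------------------------------------------------------------------------

def displays_triple(tree: RootedTree, t: RootedTriple) -> bool:
    """True iff lca(a, b) is a strict descendant of lca(a, b, c) in *tree*."""
    a, b = t.cherry
    c = t.outgroup
    lca_ab = tree.lca((a, b))
    lca_abc = tree.lca((a, b, c))
    return lca_ab is not lca_abc


def induced_triples(tree: RootedTree) -> TripleSet:
    """All rooted triples displayed by *tree* (exactly one per 3-subset
    when the tree is binary; a star tree induces none)."""
    if tree.n_leaves < 3:
        raise SetSystemError("induced triples need a tree with >= 3 leaves")
    below = tree.node_leafset()
    all_leaves = tree.leaf_labels
    out: list[RootedTriple] = []
    for node in tree.preorder():
        if node.is_leaf:
            continue
        outside = all_leaves - below[node]
        if not outside:
            outside = frozenset()
        kids = node.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                for a in below[kids[i]]:
                    for b in below[kids[j]]:
                        for c in outside:
                            out.append(RootedTriple(a, b, c))
    return TripleSet(out)


def displays_tree(parent: RootedTree, child: RootedTree) -> bool:
    """True iff *parent* displays the binary tree *child* (contains a
    subdivision of it): equivalently every triple of *child* is
    displayed by *parent*."""
    if not child.leaf_labels <= parent.leaf_labels:
        raise SetSystemError("child leaves must be a subset of parent leaves")
    if not child.is_binary:
        raise SetSystemError("display test requires a binary child tree")
    if child.n_leaves < 3:
        return True
    return all(displays_triple(parent, t) for t in induced_triples(child))


# ---------------------------------------------------------------------------
# Cluster graph and the BUILD algorithm
# ---------------------------------------------------------------------------

def cluster_graph(R: Iterable[RootedTriple], S: Iterable[str]) -> nx.Graph:
    """The graph [R, S]: vertices S, edge {a, b} for each ab|c with all
    of a, b, c in S.  Only R_S, the triples entirely inside S, matter."""
    Sset = frozenset(S)
    if not Sset:
        raise SetSystemError("cluster graph needs a non-empty vertex set")
    g = nx.Graph()
    g.add_nodes_from(sorted(Sset))
    for t in R:
        if t.labels <= Sset:
            g.add_edge(*t.cherry)
    return g


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, items: Iterable) -> None:
        self.parent = {x: x for x in items}

    def find(self, x):
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def _aho(labels: frozenset, triples: Sequence[tuple]) -> TreeNode | None:
    """BUILD recursion on (a, b, c) tuples; None signals incompatibility."""
    if len(labels) == 1:
        return TreeNode(next(iter(labels)))
    rel = [t for t in triples if t[0] in labels and t[1] in labels and t[2] in labels]
    uf = _UnionFind(labels)
    for a, b, _c in rel:
        uf.union(a, b)
    comps: dict = {}
    for x in labels:
        comps.setdefault(uf.find(x), set()).add(x)
    if len(comps) == 1:
        return None  # single component of size >= 2: incompatible
    node = TreeNode()
    for comp in sorted(comps.values(), key=min):
        child = _aho(frozenset(comp), rel)
        if child is None:
            return None
        node.add(child)
    return node


def _compatible_tuples(triples: Sequence[tuple]) -> TreeNode | None:
    labels: set = set()
    for a, b, c in triples:
        labels.update((a, b, c))
    if not labels:
        return TreeNode()
    return _aho(frozenset(labels), list(triples))


def is_compatible(R: Iterable[RootedTriple]) -> tuple[bool, RootedTree | None]:
    """Decide compatibility of a set of rooted triples via BUILD.

    Returns ``(True, tree)`` with the canonical (possibly non-binary)
    BUILD tree on L(R) that displays every triple, or ``(False, None)``.
    An empty R is compatible with a trivial tree of no leaves omitted
    (``(True, None)``).
    """
    tuples = [t.as_tuple() for t in R]
    if not tuples:
        return True, None
    root = _compatible_tuples(tuples)
    if root is None:
        return False, None
    return True, RootedTree(root)


def refine_binary(tree: RootedTree) -> RootedTree:
    """Deterministic binary refinement: each multifurcation is resolved
    as a left-leaning caterpillar over its children ordered by smallest
    descendant leaf label.  The result displays everything the input
    displays."""
    below = tree.node_leafset()

    def conv(node: TreeNode):
        if node.is_leaf:
            return node.label
        kids = sorted(node.children, key=lambda k: min(below[k]))
        parts = [conv(k) for k in kids]
        acc = parts[0]
        for nxt in parts[1:]:
            acc = (acc, nxt)
        return acc

    return RootedTree.from_nested(conv(tree.root))


# ---------------------------------------------------------------------------
# Enumeration oracles and counting
# ---------------------------------------------------------------------------

def double_factorial(k: int) -> int:
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


def _nested_shapes(labels: Sequence[str]) -> Iterator:
    """All rooted binary shapes on *labels*, by sequential leaf insertion."""
    if len(labels) == 1:
        yield labels[0]
        return
    x = labels[-1]
    for shape in _nested_shapes(labels[:-1]):
        yield from _insert_everywhere(shape, x)


def _insert_everywhere(shape, x) -> Iterator:
    yield (shape, x)  # attach above this subtree's root
    if isinstance(shape, tuple):
        l, r = shape
        for nl in _insert_everywhere(l, x):
            yield (nl, r)
        for nr in _insert_everywhere(r, x):
            yield (l, nr)


def enumerate_rooted_binary_trees(
    X: Iterable[str], *, max_leaves: int = ENUMERATION_CAP
) -> Iterator[RootedTree]:
    """Yield every rooted binary tree on X exactly once ((2n-3)!! shapes).

    Taxa are inserted in sorted order, each into every edge plus a new
    root position, giving a reproducible enumeration order.  Refused
    above ``max_leaves`` leaves.
    """
    labels = sorted(frozenset(X))
    if len(labels) < 2:
        raise SetSystemError("enumeration needs at least 2 taxa")
    if len(labels) > max_leaves:
        raise CapacityError(
            f"enumeration of {double_factorial(2 * len(labels) - 3)} trees on "
            f"{len(labels)} leaves exceeds cap {max_leaves}"
        )
    for shape in _nested_shapes(labels):
        yield RootedTree.from_nested(shape)


def _shape_triples(shape, all_leaves: frozenset) -> tuple[frozenset, frozenset]:
    """(leaf set, displayed triples as canonical tuples) of a nested shape."""
    if isinstance(shape, str):
        return frozenset((shape,)), frozenset()
    l, r = shape
    ll, lt = _shape_triples(l, all_leaves)
    rl, rt = _shape_triples(r, all_leaves)
    here = ll | rl
    outside = all_leaves - here
    new = set(lt | rt)
    for a in ll:
        for b in rl:
            lo, hi = (a, b) if a < b else (b, a)
            for c in outside:
                new.add((lo, hi, c))
    return here, frozenset(new)


@lru_cache(maxsize=8)
def _tree_triple_index(labels: tuple) -> tuple:
    """All rooted binary shapes on *labels* with their triple sets, cached."""
    all_leaves = frozenset(labels)
    return tuple(
        (shape, _shape_triples(shape, all_leaves)[1])
        for shape in _nested_shapes(list(labels))
    )


def count_displaying_trees(
    R: Iterable[RootedTriple], X: Iterable[str], *, max_leaves: int = ENUMERATION_CAP
) -> int:
    """Exact number of rooted binary trees on X displaying every triple
    of R, by exhaustive enumeration."""
    Xs = tuple(sorted(frozenset(X)))
    need = frozenset(t.as_tuple() for t in R)
    for a, b, c in need:
        for lbl in (a, b, c):
            if lbl not in Xs:
                raise SetSystemError(f"triple leaf {lbl!r} not in X")
    if len(Xs) > max_leaves:
        raise CapacityError(f"counting over {len(Xs)} leaves exceeds cap {max_leaves}")
    return sum(1 for _shape, trips in _tree_triple_index(Xs) if need <= trips)


def disjoint_display_count(n: int) -> int:
    """Closed-form count (2n-3)!!/3^(n/3) of rooted binary trees on n
    leaves displaying one triple from each of n/3 leaf-disjoint blocks."""
    if n < 3 or n % 3 != 0:
        raise SetSystemError(f"n must be a positive multiple of 3, got {n}")
    num = double_factorial(2 * n - 3)
    den = 3 ** (n // 3)
    assert num % den == 0
    return num // den


# ---------------------------------------------------------------------------
# Unique defining triples
# ---------------------------------------------------------------------------

def unique_defining_triples(tree: RootedTree) -> TripleSet:
    """A set of n-2 rooted triples displayed only by *tree*.

    Construction: pick a cherry {a, b} with parent v and grandparent u;
    take c as the smallest leaf in the component of T - u containing
    neither the root nor a, b (i.e. below the sibling of v); record
    ab|c, delete the larger cherry leaf, and recurse.  The support
    system of the result is thin, and the input tree is the unique
    rooted phylogenetic tree on its leaves displaying the result.
    """
    if not tree.is_binary:
        raise SetSystemError("unique defining triples require a binary tree")
    n = tree.n_leaves
    if n < 3:
        raise SetSystemError("need at least 3 leaves")
    if n == 3:
        return induced_triples(tree)
    below = tree.node_leafset()
    # deterministic cherry: the one whose smallest leaf label is least
    cherry_nodes = [
        node
        for node in tree.preorder()
        if len(node.children) == 2 and all(k.is_leaf for k in node.children)
    ]
    v = min(cherry_nodes, key=lambda nd: min(below[nd]))
    pair = sorted(below[v])
    b, a = pair[0], pair[1]  # delete a (the larger), keep b
    u = v.parent
    assert u is not None  # n >= 4 so a cherry's parent exists
    sibling = next(k for k in u.children if k is not v)
    c = min(below[sibling])
    rest = unique_defining_triples(tree.prune_leaf(a))
    return TripleSet(set(rest) | {RootedTriple(a, b, c)})
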