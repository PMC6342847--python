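"""Median and lca representations of thin systems by caterpillar trees.

Two certificate constructions accompany the thin criterion:

* **Median representation** (size-3 blocks): a thin system tau with
  |X| >= 4 always admits an *unrooted caterpillar* tree on X whose
  median map  s -> med_T(s)  (the unique vertex shared by the three
  pairwise leaf paths) is injective on tau.  The construction peels a
  low-occurrence taxon (one contained in at most two blocks, which a
  thin covering system always has), recurses on a reduced thin system,
  and re-inserts the taxon on the spine; every step is verified against
  the injectivity postcondition and a bounded exhaustive search over
  caterpillar leaf orderings stands behind it as a fallback.

* **lca representation** (size-2 blocks): a thin pair system admits a
  rooted binary caterpillar whose map  {x, y} -> lca(x, y)  is
  injective.

For pair systems, thinness has two further equivalent faces: the
block/taxon incidence graph G(tau) is a forest, and tau is
*total-order flexible* (every orientation of its pairs extends to a
total order on X, i.e. every orientation digraph is acyclic).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import networkx as nx

from . import set_systems, submodular
from .set_systems import (
    Block,
    CapacityError,
    SetSystem,
    SetSystemError,
    UniformityError,
    leaf_union,
)
from .trees import RootedTree, TreeNode

__all__ = [
    "UnrootedTree",
    "median_vertex",
    "is_median_injective",
    "build_caterpillar_median",
    "lca_vertex",
    "is_lca_injective",
    "build_rooted_caterpillar_lca",
    "incidence_forest_check",
    "is_total_order_flexible",
    "caterpillar_from_ordering",
    "FALLBACK_SEARCH_CAP",
    "ORDER_ENUMERATION_CEILING",
]

# Exhaustive caterpillar-ordering fallback is refused above this many taxa.
FALLBACK_SEARCH_CAP = 10
# Orientation enumeration cap for total-order flexibility.
ORDER_ENUMERATION_CEILING = 20


# ---------------------------------------------------------------------------
# Unrooted trees
# ---------------------------------------------------------------------------

class UnrootedTree:
    """An unrooted phylogenetic tree: leaves labelled (strings), interior
    vertices unlabelled (integers) of degree >= 3."""

    def __init__(self, edges: Iterable[tuple]) -> None:
        adj: dict = {}
        for u, v in edges:
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        self.adj = {k: frozenset(v) for k, v in adj.items()}
        self._check()

    def _check(self) -> None:
        if not self.adj:
            raise SetSystemError("empty tree")
        n_nodes = len(self.adj)
        n_edges = sum(len(v) for v in self.adj.values()) // 2
        if n_edges != n_nodes - 1:
            raise SetSystemError("edge set does not form a tree")
        # connectivity via BFS
        seen = {next(iter(self.adj))}
        stack = list(seen)
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != n_nodes:
            raise SetSystemError("edge set is not connected")
        for node, nbrs in self.adj.items():
            if isinstance(node, str):
                if len(nbrs) != 1:
                    raise SetSystemError(f"leaf {node!r} must have degree 1")
            elif len(nbrs) < 3:
                raise SetSystemError(f"interior vertex {node!r} has degree < 3")

    @property
    def leaves(self) -> frozenset:
        return frozenset(n for n in self.adj if isinstance(n, str))

    @property
    def interior(self) -> frozenset:
        return frozenset(n for n in self.adj if not isinstance(n, str))

    @property
    def is_binary(self) -> bool:
        return all(len(self.adj[v]) == 3 for v in self.interior)

    def cherries(self) -> list[frozenset]:
        out = []
        for v in self.interior:
            leaf_nbrs = [u for u in self.adj[v] if isinstance(u, str)]
            for pair in itertools.combinations(sorted(leaf_nbrs), 2):
                out.append(frozenset(pair))
        return out

    @property
    def is_caterpillar(self) -> bool:
        """Binary with at most two cherries (interior vertices on a path)."""
        return self.is_binary and len(self.cherries()) <= 2

    def path(self, a, b) -> list:
        """The unique path from node a to node b."""
        prev = {a: None}
        stack = [a]
        while stack:
            u = stack.pop()
            if u == b:
                break
            for v in self.adj[u]:
                if v not in prev:
                    prev[v] = u
                    stack.append(v)
        if b not in prev:
            raise SetSystemError(f"no path between {a!r} and {b!r}")
        out = [b]
        while out[-1] != a:
            out.append(prev[out[-1]])
        return out[::-1]

    def to_newick(self) -> str:
        """Newick rooted at the neighbour of the smallest leaf, prefixed
        with the conventional [&U] flag for unrooted semantics."""
        first = min(self.leaves)
        root = next(iter(self.adj[first]))

        def fmt(node, parent) -> str:
            kids = sorted(
                (v for v in self.adj[node] if v != parent),
                key=lambda v: self._min_leaf(v, node),
            )
            if isinstance(node, str):
                return node
            return "(" + ",".join(fmt(k, node) for k in kids) + ")"

        return "[&U] " + fmt(root, None) + ";"

    def _min_leaf(self, node, parent) -> str:
        if isinstance(node, str):
            return node
        return min(self._min_leaf(v, node) for v in self.adj[node] if v != parent)

    def __repr__(self) -> str:
        return f"UnrootedTree({self.to_newick()!r})"


def median_vertex(tree: UnrootedTree, s: Iterable[str]):
    """The median of three leaves: the unique vertex shared by their
    three pairwise paths (the divergence point of the paths from the
    first leaf to the other two)."""
    a, b, c = sorted(frozenset(s))
    for x in (a, b, c):
        if x not in tree.leaves:
            raise SetSystemError(f"{x!r} is not a leaf of this tree")
    pab = tree.path(a, b)
    pac = tree.path(a, c)
    med = a
    for u, v in zip(pab, pac):
        if u != v:
            break
        med = u
    return med


def is_median_injective(tree: UnrootedTree, system: SetSystem) -> bool:
    """True iff distinct blocks map to distinct median vertices."""
    if system.uniform_size != 3:
        raise UniformityError("median representation applies to size-3 blocks")
    meds = [median_vertex(tree, b) for b in system.blocks]
    return len(set(meds)) == len(meds)


# ---------------------------------------------------------------------------
# Caterpillars from leaf orderings
# ---------------------------------------------------------------------------

def caterpillar_from_ordering(order: Sequence[str]) -> UnrootedTree:
    """Unrooted caterpillar with leaves in spine order.

    ``order[0], order[1]`` form one end cherry and ``order[-2],
    order[-1]`` the other; interior vertices are integers 0..n-3.
    A 3-leaf ordering gives the unique star on three leaves.
    """
    n = len(order)
    if n < 3:
        raise SetSystemError("caterpillar needs at least 3 leaves")
    if len(set(order)) != n:
        raise SetSystemError("duplicate leaves in ordering")
    edges: list[tuple] = []
    if n == 3:
        return UnrootedTree([(order[0], 0), (order[1], 0), (order[2], 0)])
    for j in range(n - 3):
        edges.append((j, j + 1))
    edges.append((order[0], 0))
    edges.append((order[1], 0))
    for i in range(2, n - 1):
        edges.append((order[i], i - 1))
    edges.append((order[n - 1], n - 3))
    return UnrootedTree(edges)


def _spine_index(n: int, pos: int) -> int:
    """Interior vertex index adjacent to the leaf at position *pos*."""
    if n <= 3 or pos <= 1:
        return 0
    if pos == n - 1:
        return n - 3
    return pos - 1


def _ordering_injective(order: Sequence[str], blocks: Iterable[Block]) -> bool:
    """Median injectivity test on a caterpillar ordering without building
    the tree: the median of a block is the spine vertex of its middle
    leaf along the ordering."""
    pos = {x: i for i, x in enumerate(order)}
    n = len(order)
    seen: set[int] = set()
    for b in blocks:
        try:
            ps = sorted(pos[x] for x in b)
        except KeyError:
            return False
        med = _spine_index(n, ps[1])
        if med in seen:
            return False
        seen.add(med)
    return True


# ---------------------------------------------------------------------------
# Median caterpillar construction
# ---------------------------------------------------------------------------

def _check_thin_blocks(blocks: Sequence[Block]) -> bool:
    sys = SetSystem(blocks)
    if len(blocks) <= set_systems.AUTO_POLY_THRESHOLD:
        ok, _ = set_systems.is_thin(sys, method="brute")
        return ok
    return submodular.is_thin_poly(sys)


def _construct_ordering(blocks: list) -> list | None:
    """Proof-guided recursion: peel a taxon occurring in <= 2 blocks,
    solve the reduced thin system, re-insert on the spine.  Every
    re-insertion position is tried and verified; candidate merged
    blocks that break thinness are skipped.  Returns a verified
    ordering or None."""
    taxa = sorted(leaf_union(blocks))
    if not blocks:
        return taxa
    if len(blocks) == 1:
        return taxa
    counts = {x: 0 for x in taxa}
    for b in blocks:
        for x in b:
            counts[x] += 1

    def finish(sub: list | None, removed: frozenset, x: str) -> list | None:
        if sub is None:
            return None
        missing = sorted(set(removed) - set(sub) - {x})
        base = sub + missing
        for i in range(len(base) + 1):
            cand = base[:i] + [x] + base[i:]
            if _ordering_injective(cand, blocks):
                return cand
        return None

    # Case A: a taxon in exactly one block
    for x in (t for t in taxa if counts[t] == 1):
        t = next(b for b in blocks if x in b)
        rest = [b for b in blocks if b != t]
        out = finish(_construct_ordering(rest), t, x)
        if out is not None:
            return out
    # Case B: a taxon in exactly two blocks; replace the pair by a
    # merged 3-block containing the leftover structure, recurse, re-insert
    for x in (t for t in taxa if counts[t] == 2):
        t1, t2 = (b for b in blocks if x in b)
        others1 = sorted(t1 - {x})
        others2 = sorted(t2 - {x})
        overlap = set(others1) & set(others2)
        candidates: list[frozenset] = []
        if len(overlap) == 1:
            candidates.append(frozenset(set(others1) | set(others2)))
        else:
            for pair, single_src in ((others1, others2), (others2, others1)):
                for single in single_src:
                    candidates.append(frozenset([*pair, single]))
        removed = (t1 | t2) - {x}
        for merged in candidates:
            new_blocks = [b for b in blocks if b not in (t1, t2)]
            if merged not in new_blocks:
                new_blocks.append(merged)
            new_blocks.sort(key=lambda b: tuple(sorted(b)))
            if not _check_thin_blocks(new_blocks):
                continue
            out = finish(_construct_ordering(new_blocks), removed, x)
            if out is not None:
                return out
    return None


def _search_ordering(taxa: Sequence[str], blocks: Sequence[Block]) -> list | None:
    """Exhaustive fallback over caterpillar leaf orderings (reversal
    symmetry halved); correctness of the construction is defined by
    this verified postcondition, not by the recursion's letter."""
    taxa = sorted(taxa)
    if len(taxa) > FALLBACK_SEARCH_CAP:
        raise CapacityError(
            f"ordering search over {len(taxa)}! permutations exceeds cap "
            f"{FALLBACK_SEARCH_CAP} taxa"
        )
    for perm in itertools.permutations(taxa):
        if perm[0] > perm[-1]:
            continue
        if _ordering_injective(perm, blocks):
            return list(perm)
    return None


def build_caterpillar_median(system: SetSystem) -> UnrootedTree:
    """An unrooted caterpillar on the universe whose median map is
    injective on the blocks (a median representation).

    Requires a thin, uniform size-3 system with a universe of at least
    4 taxa; non-thin input raises with the negative-excess witness.
    Taxa of the universe outside L(tau) are appended beyond the last
    interior vertex of the spine, where they cannot collide with any
    block median.
    """
    if system.require_uniform() != 3:
        raise UniformityError("median caterpillar applies to size-3 systems")
    if len(system.universe) < 4:
        raise SetSystemError("median caterpillar needs a universe of >= 4 taxa")
    thin, report = set_systems.is_thin(system)
    if not thin:
        raise SetSystemError(
            f"system is not thin: subset {[sorted(b) for b in report.subset]} "
            f"has excess {report.excess}"
        )
    blocks = list(system.blocks)
    order = _construct_ordering(blocks)
    extras = sorted(system.universe - leaf_union(blocks))
    if order is not None:
        order = order + extras
        if not _ordering_injective(order, blocks):
            order = None
    if order is None:
        order = _search_ordering(sorted(system.universe), blocks)
    if order is None:
        # Unreachable for thin input (a caterpillar representation always
        # exists); defensive guard for the capped search path.
        raise SetSystemError("no caterpillar ordering found")
    tree = caterpillar_from_ordering(order)
    assert tree.is_caterpillar and is_median_injective(tree, system)
    return tree


# ---------------------------------------------------------------------------
# lca representation for pair systems
# ---------------------------------------------------------------------------

def lca_vertex(tree: RootedTree, pair: Iterable[str]) -> TreeNode:
    """Least common ancestor of a pair of leaves in a rooted tree."""
    pair = sorted(frozenset(pair))
    if len(pair) != 2:
        raise SetSystemError("lca_vertex expects a pair of distinct leaves")
    return tree.lca(pair)


def is_lca_injective(tree: RootedTree, system: SetSystem) -> bool:
    """True iff distinct pair blocks map to distinct lca vertices."""
    lcas = [lca_vertex(tree, b) for b in system.blocks]
    return len({id(v) for v in lcas}) == len(lcas)


def _rooted_caterpillar(order: Sequence[str]) -> RootedTree:
    if len(order) < 2:
        raise SetSystemError("rooted caterpillar needs >= 2 leaves")
    nested = order[0]
    for x in order[1:]:
        nested = (nested, x)
    return RootedTree.from_nested(nested)


def _lca_ordering(blocks: list) -> list:
    """Peel a taxon occurring in exactly one pair; the reduced system
    loses either one taxon or two, and the peeled taxa re-attach above
    the recursive caterpillar's root."""
    if len(blocks) == 1:
        return sorted(next(iter(blocks)))
    counts: dict[str, int] = {}
    for b in blocks:
        for t in b:
            counts[t] = counts.get(t, 0) + 1
    solo = sorted(t for t, c in counts.items() if c == 1)
    if not solo:
        raise SetSystemError("no taxon of occurrence 1: system is not thin")
    x = solo[0]
    pair = next(b for b in blocks if x in b)
    (a,) = sorted(pair - {x})
    rest = [b for b in blocks if b != pair]
    sub = _lca_ordering(rest)
    if a in sub:
        return sub + [x]
    return sub + [a, x]


def build_rooted_caterpillar_lca(system: SetSystem) -> RootedTree:
    """A rooted binary caterpillar on X whose lca map is injective on a
    thin pair system covering X."""
    if system.require_uniform() != 2:
        raise UniformityError("lca caterpillar applies to size-2 systems")
    if system.leaves != system.universe:
        raise SetSystemError("lca caterpillar assumes the system covers its universe")
    thin, report = set_systems.is_thin(system)
    if not thin:
        raise SetSystemError(
            f"system is not thin: subset {[sorted(b) for b in report.subset]} "
            f"has excess {report.excess}"
        )
    order = _lca_ordering(list(system.blocks))
    tree = _rooted_caterpillar(order)
    assert tree.is_caterpillar and is_lca_injective(tree, system)
    return tree


# ---------------------------------------------------------------------------
# Pair-system criteria: forest and total-order flexibility
# ---------------------------------------------------------------------------

def incidence_forest_check(system: SetSystem) -> bool:
    """Thinness of a pair system via its incidence graph: tau (size-2
    blocks, covering its universe) is thin iff G(tau) is a forest."""
    if system.require_uniform() != 2:
        raise UniformityError("forest criterion applies to size-2 systems")
    inc = submodular.BipartiteIncidence.from_system(system, mode="sigma")
    g = inc.to_graph()
    return nx.is_forest(g)


def _orientation_acyclic(orientation: Sequence[tuple]) -> bool:
    succ: dict[str, set] = {}
    indeg: dict[str, int] = {}
    for lo, hi in orientation:
        succ.setdefault(lo, set())
        succ.setdefault(hi, set())
        if hi not in succ[lo]:
            succ[lo].add(hi)
            indeg[hi] = indeg.get(hi, 0) + 1
        indeg.setdefault(lo, indeg.get(lo, 0))
    queue = [v for v, d in indeg.items() if d == 0]
    seen = 0
    while queue:
        v = queue.pop()
        seen += 1
        for w in succ[v]:
            indeg[w] -= 1
            if indeg[w] == 0:
                queue.append(w)
    return seen == len(succ)


def is_total_order_flexible(
    system: SetSystem,
    method: str = "exhaustive",
    *,
    max_blocks: int = ORDER_ENUMERATION_CEILING,
) -> tuple[bool, dict | None]:
    """Decide total-order flexibility of a pair system.

    An orientation assigns a direction x < y to each pair; it extends
    to a total order on X iff its digraph is acyclic.  The exhaustive
    route tries all 2^|tau| orientations and, on failure, returns a
    cyclic counterexample orientation as ``{block: (smaller, larger)}``;
    the ``"thin"`` route applies the excess criterion; ``"both"``
    cross-validates.
    """
    if system.require_uniform() != 2:
        raise UniformityError("total-order flexibility applies to size-2 systems")
    if method == "thin":
        thin, _ = set_systems.is_thin(system)
        return thin, None
    if method not in ("exhaustive", "both"):
        raise ValueError(f"unknown method: {method!r}")
    if len(system) > max_blocks:
        raise CapacityError(
            f"orientation enumeration over 2^{len(system)} exceeds cap 2^{max_blocks}"
        )
    blocks = system.blocks
    verdict, witness = True, None
    for choice in itertools.product((0, 1), repeat=len(blocks)):
        orientation = []
        for b, flip in zip(blocks, choice):
            x, y = sorted(b)
            orientation.append((y, x) if flip else (x, y))
        if not _orientation_acyclic(orientation):
            verdict, witness = False, dict(zip(blocks, orientation))
            break
    if method == "both":
        thin, _ = set_systems.is_thin(system)
        if thin != verdict:
            raise AssertionError(
                f"thin criterion ({thin}) disagrees with exhaustive "
                f"total-order flexibility ({verdict})"
            )
    return verdict, witness
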