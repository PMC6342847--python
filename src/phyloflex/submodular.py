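"""Submodular coverage functions and polynomial-time thin/slim decisions.

For a set system tau define, over sub-collections tau' of its blocks,

    sigma(tau') = |L(tau')| - |tau'|
    gamma(tau') = |L(tau')| - sum_{s in tau'} (|s| - 2)

with sigma(empty) = gamma(empty) = 0.  Both are submodular.  On
non-empty sub-collections sigma = exc + (r - 1) for r-uniform systems
and gamma = exc' + 2, so the sparsity criteria become threshold tests
on the minima

    sigma*(tau) = min over non-empty tau' of sigma(tau')
    gamma*(tau) = min over non-empty tau' of gamma(tau'):

tau (r-uniform) is thin iff sigma* >= r - 1 (the familiar sigma* >= 2
at r = 3), and tau (blocks >= 3) is slim iff gamma* >= 2.

Minimisation is done in polynomial time by a forced-element min-cut
construction on the block/taxon incidence graph: for each block s,
build the flow network  source -> block (capacity = block weight,
infinite for the forced s), block -> taxon (infinite, for containment
edges), taxon -> sink (capacity 1).  A minimum source/sink cut keeps a
set Y of blocks (containing s) on the source side and must cut the
unit edges of all taxa they cover, so

    min cut  =  (total block weight) - weight(Y) + |N(Y)|,

i.e. min over Y containing s of |N(Y)| - weight(Y) equals the min cut
minus the total weight.  Taking the minimum over all forced s yields
sigma* (unit weights) or gamma* (weights |s| - 2).  Subset enumeration
remains available as the independent brute-force oracle.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import networkx as nx

from .set_systems import (
    Block,
    BlockSizeError,
    CapacityError,
    SetSystem,
    SetSystemError,
    leaf_union,
)

__all__ = [
    "BipartiteIncidence",
    "MinimizerResult",
    "sigma",
    "gamma",
    "check_submodularity",
    "sigma_star",
    "gamma_star",
    "is_thin_poly",
    "is_slim_poly",
    "graph_surplus",
    "degree2_forest_exists",
]


def sigma(subset: Iterable[Block]) -> int:
    """sigma(tau') = |L(tau')| - |tau'|; 0 on the empty sub-collection."""
    blocks = list(subset)
    if not blocks:
        return 0
    return len(leaf_union(blocks)) - len(blocks)


def gamma(subset: Iterable[Block]) -> int:
    """gamma(tau') = |L(tau')| - sum (|s| - 2); 0 on the empty sub-collection."""
    blocks = list(subset)
    if not blocks:
        return 0
    return len(leaf_union(blocks)) - sum(len(b) - 2 for b in blocks)


@dataclass(frozen=True)
class BipartiteIncidence:
    """The containment graph G(tau) between blocks (side A) and taxa (side B).

    ``weights`` carries one positive integer per block: 1 for sigma
    minimisation, |s| - 2 for gamma.
    """

    blocks: tuple
    taxa: frozenset
    weights: tuple

    @classmethod
    def from_system(cls, system: SetSystem, mode: str = "sigma") -> "BipartiteIncidence":
        if mode == "sigma":
            w = tuple(1 for _ in system.blocks)
        elif mode == "gamma":
            for b in system.blocks:
                if len(b) < 3:
                    raise BlockSizeError(
                        f"gamma weights need blocks of size >= 3, got {sorted(b)}"
                    )
            w = tuple(len(b) - 2 for b in system.blocks)
        else:
            raise ValueError(f"unknown weight mode: {mode!r}")
        return cls(blocks=system.blocks, taxa=system.leaves, weights=w)

    def neighbourhood(self, Y: Iterable[Block]) -> frozenset:
        """N(Y): taxa contained in at least one block of Y."""
        return leaf_union(Y)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for i, b in enumerate(self.blocks):
            g.add_node(("block", i), bipartite=0)
            for x in b:
                g.add_edge(("block", i), ("taxon", x))
        for x in self.taxa:
            g.add_node(("taxon", x), bipartite=1)
        return g


@dataclass(frozen=True)
class MinimizerResult:
    """Value and attaining non-empty sub-collection of a sigma/gamma minimum."""

    value: int
    argmin: tuple


def _weight_fn(mode: str) -> Callable[[Sequence[Block]], int]:
    if mode == "sigma":
        return len
    return lambda blocks: sum(len(b) - 2 for b in blocks)


def _brute_star(blocks: Sequence[Block], mode: str) -> MinimizerResult:
    wfn = _weight_fn(mode)
    best = None
    best_sub = None
    idx = range(len(blocks))
    for k in range(1, len(blocks) + 1):
        for comb in itertools.combinations(idx, k):
            sub = [blocks[i] for i in comb]
            val = len(leaf_union(sub)) - wfn(sub)
            if best is None or val < best:
                best, best_sub = val, tuple(sub)
    assert best is not None
    return MinimizerResult(value=best, argmin=best_sub)


def _mincut_star(system: SetSystem, mode: str) -> MinimizerResult:
    inc = BipartiteIncidence.from_system(system, mode)
    blocks, weights = inc.blocks, inc.weights
    total_w = sum(weights)
    inf = total_w + sum(len(b) for b in blocks) + 1
    best: int | None = None
    best_sub: tuple | None = None
    for forced in range(len(blocks)):
        g = nx.DiGraph()
        for i, b in enumerate(blocks):
            cap = inf if i == forced else weights[i]
            g.add_edge("src", ("block", i), capacity=cap)
            for x in b:
                g.add_edge(("block", i), ("taxon", x), capacity=inf)
        for x in inc.taxa:
            g.add_edge(("taxon", x), "snk", capacity=1)
        cut_value, (src_side, _snk_side) = nx.minimum_cut(g, "src", "snk")
        value = cut_value - total_w
        if best is None or value < best:
            best = value
            best_sub = tuple(
                blocks[i]
                for i in range(len(blocks))
                if ("block", i) in src_side
            )
    assert best is not None and best_sub
    # the reported value must equal the function recomputed on the argmin
    wfn = _weight_fn(mode)
    recomputed = len(leaf_union(best_sub)) - wfn(list(best_sub))
    assert recomputed == best, (recomputed, best)
    return MinimizerResult(value=best, argmin=best_sub)


def _star(system: SetSystem, mode: str, method: str) -> MinimizerResult:
    if not system.blocks:
        raise SetSystemError("sigma*/gamma* need a non-empty system")
    if mode == "gamma":
        for b in system.blocks:
            if len(b) < 3:
                raise BlockSizeError(
                    f"gamma* requires blocks of size >= 3, got {sorted(b)}"
                )
    if method == "brute":
        return _brute_star(system.blocks, mode)
    if method == "mincut":
        return _mincut_star(system, mode)
    if method == "both":
        brute = _brute_star(system.blocks, mode)
        cut = _mincut_star(system, mode)
        if brute.value != cut.value:
            raise AssertionError(
                f"min-cut/{mode} disagreement: brute {brute.value}, mincut {cut.value}"
            )
        return cut
    raise ValueError(f"unknown method: {method!r}")


def sigma_star(system: SetSystem, method: str = "mincut") -> MinimizerResult:
    """Minimum of sigma over non-empty sub-collections, with an argmin.

    ``method``: "brute" enumerates subsets, "mincut" runs the
    forced-element min-cut construction, "both" cross-validates.
    """
    return _star(system, "sigma", method)


def gamma_star(system: SetSystem, method: str = "mincut") -> MinimizerResult:
    """Minimum of gamma over non-empty sub-collections (blocks >= 3)."""
    return _star(system, "gamma", method)


def is_thin_poly(system: SetSystem) -> bool:
    """Thin decision via sigma*: thin iff sigma* >= r - 1.

    For r = 3 this is the sigma* >= 2 criterion; the same identity
    exc = sigma - (r - 1) gives the threshold for every uniform size,
    including pair systems (r = 2, threshold 1).
    """
    r = system.require_uniform()
    return sigma_star(system, method="mincut").value >= r - 1


def is_slim_poly(system: SetSystem) -> bool:
    """Slim decision via gamma*: slim iff gamma* >= 2."""
    return gamma_star(system, method="mincut").value >= 2


def check_submodularity(
    system: SetSystem, trials: int = 200, seed: int = 0
) -> bool:
    """Verify f(A) + f(B) >= f(A u B) + f(A n B) for sigma and gamma.

    Exhaustive over all subset pairs for systems of <= 8 blocks, random
    sampling (seeded) otherwise.  Always true for these coverage
    functions; exposed as a checkable property.
    """
    blocks = system.blocks
    gamma_ok = all(len(b) >= 2 for b in blocks)

    def both_hold(A: frozenset, B: frozenset) -> bool:
        for f in (sigma, gamma) if gamma_ok else (sigma,):
            if f(A) + f(B) < f(A | B) + f(A & B):
                return False
        return True

    if len(blocks) <= 8:
        subsets = [
            frozenset(c)
            for k in range(len(blocks) + 1)
            for c in itertools.combinations(blocks, k)
        ]
        return all(
            both_hold(A, B) for A, B in itertools.combinations_with_replacement(subsets, 2)
        )
    rng = random.Random(seed)
    for _ in range(trials):
        A = frozenset(b for b in blocks if rng.random() < 0.5)
        B = frozenset(b for b in blocks if rng.random() < 0.5)
        if not both_hold(A, B):
            return False
    return True


def graph_surplus(G: BipartiteIncidence) -> int:
    """Minimum surplus |N(Y)| - |Y| over non-empty block sets Y of G.

    Equals sigma* of the generating system; positive surplus (viewed
    from the block side) characterises thinness of pair systems and,
    via the threshold r - 1, uniform systems generally.
    """
    if not G.blocks:
        raise SetSystemError("surplus needs a non-empty block side")
    best = None
    idx = range(len(G.blocks))
    for k in range(1, len(G.blocks) + 1):
        for comb in itertools.combinations(idx, k):
            sub = [G.blocks[i] for i in comb]
            val = len(leaf_union(sub)) - len(sub)
            if best is None or val < best:
                best = val
    assert best is not None
    return best


def degree2_forest_exists(G: BipartiteIncidence, *, max_edges: int = 20) -> bool:
    """Does G contain a forest F with deg_F(block) = 2 for every block?

    Equivalent to G having positive surplus (viewed from the block
    side).  Brute-force test utility: picks two incident edges per
    block in all possible ways and checks acyclicity; refused above
    ``max_edges`` containment edges.
    """
    n_edges = sum(len(b) for b in G.blocks)
    if n_edges > max_edges:
        raise CapacityError(
            f"forest search over {n_edges} edges exceeds cap {max_edges}"
        )
    if any(len(b) < 2 for b in G.blocks):
        return False
    per_block = [
        list(itertools.combinations(sorted(b), 2)) for b in G.blocks
    ]
    for choice in itertools.product(*per_block):
        g = nx.Graph()
        g.add_nodes_from(("taxon", x) for x in G.taxa)
        for i, (x, y) in enumerate(choice):
            g.add_edge(("block", i), ("taxon", x))
            g.add_edge(("block", i), ("taxon", y))
        if nx.is_forest(g):
            return True
    return False
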