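"""Set systems of taxon subsets and their Hall-type excess criteria.

A *set system* is a collection tau of distinct subsets ("blocks") of a
finite taxon set X.  Each block is the leaf set of some input phylogeny;
the system records only the taxon-coverage pattern, not the trees.  Two
sparsity conditions on tau govern whether *every* choice of trees on
those leaf sets can be combined into a common supertree:

* **thin** (uniform block size r): every non-empty sub-collection tau'
  satisfies ``exc(tau') = |L(tau')| - |tau'| - (r - 1) >= 0``, where
  L(tau') is the union of the blocks in tau'.
* **slim** (block sizes >= 3, possibly mixed): every non-empty tau'
  satisfies ``exc'(tau') = |L(tau')| - 2 - sum_s (|s| - 2) >= 0``.

For uniform size-3 systems the two notions coincide; for uniform size
r > 3 slim is strictly stronger than thin.

This module holds the data model, the excess functions, brute-force
deciders with minimum-excess witnesses, occurrence counts, the
system-of-distinct-representatives utility, and the patchwork closure
check for the family of zero-excess sub-collections.  Polynomial-time
decisions delegate to :mod:`phyloflex.submodular`.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "Block",
    "SetSystem",
    "ExcessReport",
    "SetSystemError",
    "UniformityError",
    "BlockSizeError",
    "CapacityError",
    "make_block",
    "leaf_union",
    "excess_uniform",
    "excess_general",
    "is_thin",
    "is_slim",
    "occurrence_counts",
    "has_sdr_after_deletion",
    "zero_excess_family_is_patchwork",
    "validate_label",
    "BRUTE_FORCE_CEILING",
    "AUTO_POLY_THRESHOLD",
]

# Enumeration guards: brute-force subset enumeration is refused above
# BRUTE_FORCE_CEILING blocks unless the caller raises the cap; "auto"
# deciders switch to the polynomial route above AUTO_POLY_THRESHOLD.
BRUTE_FORCE_CEILING = 20
AUTO_POLY_THRESHOLD = 15

_LABEL_RE = re.compile(r"^[^\s,|();]+$")


class SetSystemError(ValueError):
    """Base class for set-system construction and precondition errors."""


class UniformityError(SetSystemError):
    """Raised when an operation requiring uniform block size meets mixed sizes."""


class BlockSizeError(SetSystemError):
    """Raised when a block violates a minimum-size requirement."""


class CapacityError(SetSystemError):
    """Raised when a brute-force enumeration would exceed its configured cap."""


def validate_label(label: str) -> str:
    """Check that *label* is a legal taxon token and return it.

    Labels must be non-empty and free of whitespace, commas, pipes,
    parentheses and semicolons so that they survive the text and Newick
    serialisations unescaped.
    """
    if not isinstance(label, str) or not _LABEL_RE.match(label):
        raise SetSystemError(f"invalid taxon label: {label!r}")
    return label


#: A block is an immutable set of taxon labels (size >= 2).
Block = frozenset


def make_block(members: Iterable[str]) -> Block:
    """Build a validated block from an iterable of taxon labels."""
    mem = frozenset(validate_label(m) for m in members)
    if len(mem) < 2:
        raise BlockSizeError(f"block needs >= 2 distinct taxa, got {sorted(mem)}")
    return mem


def _block_key(block: Block) -> tuple:
    return tuple(sorted(block))


def leaf_union(blocks: Iterable[Block]) -> frozenset:
    """Union of the blocks: the taxa covered by at least one block (L)."""
    out: set = set()
    for b in blocks:
        out |= b
    return frozenset(out)


class SetSystem:
    """A collection of distinct taxon subsets over a universe X.

    Parameters
    ----------
    blocks:
        Iterable of iterables of taxon labels.  Blocks must be pairwise
        distinct as sets (``dedupe=True`` drops duplicates with a
        warning instead of raising).
    universe:
        Optional taxon universe; defaults to the union of the blocks.
        Every block must be contained in it.
    """

    __slots__ = ("blocks", "universe")

    def __init__(
        self,
        blocks: Iterable[Iterable[str]],
        universe: Iterable[str] | None = None,
        *,
        dedupe: bool = False,
    ) -> None:
        made = [make_block(b) for b in blocks]
        seen: dict[Block, None] = {}
        for b in made:
            if b in seen:
                if dedupe:
                    warnings.warn(f"duplicate block {sorted(b)} dropped", stacklevel=2)
                    continue
                raise SetSystemError(f"duplicate block: {sorted(b)}")
            seen[b] = None
        self.blocks: tuple[Block, ...] = tuple(sorted(seen, key=_block_key))
        covered = leaf_union(self.blocks)
        if universe is None:
            self.universe: frozenset = covered
        else:
            self.universe = frozenset(validate_label(u) for u in universe)
            if not covered <= self.universe:
                missing = sorted(covered - self.universe)
                raise SetSystemError(f"blocks use taxa outside universe: {missing}")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SetSystem):
            return NotImplemented
        return self.blocks == other.blocks and self.universe == other.universe

    def __hash__(self) -> int:
        return hash((self.blocks, self.universe))

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(sorted(b)) + "}" for b in self.blocks)
        return f"SetSystem([{inner}], n={len(self.universe)})"

    # -- derived quantities ---------------------------------------------
    @property
    def leaves(self) -> frozenset:
        """L(tau): taxa appearing in at least one block."""
        return leaf_union(self.blocks)

    @property
    def uniform_size(self) -> int | None:
        """The common block size r, or None if sizes are mixed."""
        sizes = {len(b) for b in self.blocks}
        return sizes.pop() if len(sizes) == 1 else None

    def require_uniform(self) -> int:
        r = self.uniform_size
        if r is None:
            raise UniformityError(
                f"operation requires uniform block size; sizes present: "
                f"{sorted({len(b) for b in self.blocks})}"
            )
        return r

    def restrict(self, blocks: Iterable[Block]) -> "SetSystem":
        """Sub-system on the given blocks (universe preserved)."""
        return SetSystem(blocks, universe=self.universe)


@dataclass(frozen=True)
class ExcessReport:
    """Witness record: a sub-collection of blocks and its excess.

    ``mode`` is ``"uniform"`` (exc, needs a uniform size r) or
    ``"general"`` (exc', block sizes >= 3).  The stored excess always
    equals the recomputed excess of ``subset`` under ``mode``.
    """

    subset: tuple[Block, ...]
    excess: int
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "general"):
            raise ValueError(f"unknown excess mode: {self.mode}")
        if self.subset:
            if self.mode == "uniform":
                r = len(self.subset[0])
                got = excess_uniform(self.subset, r)
            else:
                got = excess_general(self.subset)
            if got != self.excess:
                raise ValueError(
                    f"inconsistent ExcessReport: stored {self.excess}, recomputed {got}"
                )


def excess_uniform(subset: Sequence[Block] | Iterable[Block], r: int) -> int:
    """exc of a non-empty r-uniform sub-collection: |L| - |tau'| - (r - 1)."""
    blocks = list(subset)
    if not blocks:
        raise SetSystemError("excess of the empty sub-collection is undefined")
    if r < 2:
        raise SetSystemError(f"block size r must be >= 2, got {r}")
    for b in blocks:
        if len(b) != r:
            raise UniformityError(f"block {sorted(b)} has size {len(b)}, expected r={r}")
    return len(leaf_union(blocks)) - len(blocks) - (r - 1)


def excess_general(subset: Sequence[Block] | Iterable[Block]) -> int:
    """exc' of a non-empty sub-collection: |L| - 2 - sum over blocks of (|s| - 2).

    Agrees with ``excess_uniform(subset, 3)`` on uniform size-3 input.
    """
    blocks = list(subset)
    if not blocks:
        raise SetSystemError("excess of the empty sub-collection is undefined")
    for b in blocks:
        if len(b) < 3:
            raise BlockSizeError(f"exc' requires blocks of size >= 3, got {sorted(b)}")
    return len(leaf_union(blocks)) - 2 - sum(len(b) - 2 for b in blocks)


def _iter_subsets(blocks: Sequence[Block]) -> Iterator[tuple[int, ...]]:
    """Non-empty index subsets in (size, lexicographic) order."""
    idx = range(len(blocks))
    for k in range(1, len(blocks) + 1):
        yield from itertools.combinations(idx, k)


def _brute_min_excess(blocks: Sequence[Block], excess) -> tuple[int, tuple[Block, ...]]:
    """Minimum excess over non-empty subsets, with the first-attaining witness.

    The enumeration order (subset size ascending, then lexicographic on
    canonical block order) makes the returned witness the canonical,
    deterministic one among all minimisers.
    """
    best: int | None = None
    best_idx: tuple[int, ...] | None = None
    for comb in _iter_subsets(blocks):
        e = excess([blocks[i] for i in comb])
        if best is None or e < best:
            best, best_idx = e, comb
    assert best is not None and best_idx is not None
    return best, tuple(blocks[i] for i in best_idx)


def _decide(
    system: SetSystem,
    mode: str,
    method: str,
    max_bruteforce: int,
) -> tuple[bool, ExcessReport]:
    if not system.blocks:
        raise SetSystemError("cannot decide thin/slim for an empty system")
    if mode == "uniform":
        r = system.require_uniform()
        excess = lambda sub: excess_uniform(sub, r)  # noqa: E731
    else:
        for b in system.blocks:
            if len(b) < 3:
                raise BlockSizeError(
                    f"slim requires blocks of size >= 3, got {sorted(b)}"
                )
        excess = excess_general

    if method == "auto":
        method = "poly" if len(system) > AUTO_POLY_THRESHOLD else "brute"

    if method == "brute":
        if len(system) > max_bruteforce:
            raise CapacityError(
                f"brute-force enumeration over {len(system)} blocks exceeds cap "
                f"{max_bruteforce}; use method='poly' or raise max_bruteforce"
            )
        value, witness = _brute_min_excess(system.blocks, excess)
        report = ExcessReport(subset=witness, excess=value, mode=mode)
        return value >= 0, report
    if method == "poly":
        from . import submodular

        if mode == "uniform":
            res = submodular.sigma_star(system, method="mincut")
            # sigma = exc + (r - 1) - ... : sigma(tau') = |L| - |tau'|, so
            # exc = sigma - (r - 1); thin  <=>  sigma* >= r - 1 + 0.
            # For the report we recompute exc on the argmin directly.
            value = excess([*res.argmin])
        else:
            res = submodular.gamma_star(system, method="mincut")
            value = excess([*res.argmin])
        report = ExcessReport(subset=tuple(res.argmin), excess=value, mode=mode)
        return _poly_verdict(system, mode), report
    raise ValueError(f"unknown method: {method!r}")


def _poly_verdict(system: SetSystem, mode: str) -> bool:
    from . import submodular

    if mode == "uniform":
        return submodular.is_thin_poly(system)
    return submodular.is_slim_poly(system)


def is_thin(
    system: SetSystem,
    method: str = "auto",
    *,
    max_bruteforce: int = BRUTE_FORCE_CEILING,
) -> tuple[bool, ExcessReport]:
    """Decide thinness of a uniform set system.

    Returns ``(verdict, report)`` where the report carries a
    minimum-excess sub-collection: for a non-thin system this is a
    negative-excess witness, for a thin system a minimiser certifying
    that the minimum is non-negative.

    ``method`` is ``"brute"`` (enumerate all non-empty subsets),
    ``"poly"`` (min-cut submodular minimisation, see
    :func:`phyloflex.submodular.sigma_star`) or ``"auto"``.
    """
    return _decide(system, "uniform", method, max_bruteforce)


def is_slim(
    system: SetSystem,
    method: str = "auto",
    *,
    max_bruteforce: int = BRUTE_FORCE_CEILING,
) -> tuple[bool, ExcessReport]:
    """Decide slimness (mixed-size excess exc') of a set system.

    Requires all blocks of size >= 3.  For uniform size-3 systems the
    verdict coincides with :func:`is_thin`; for uniform size r > 3 slim
    implies thin but not conversely.
    """
    return _decide(system, "general", method, max_bruteforce)


def occurrence_counts(system: SetSystem) -> dict:
    """n_tau(x): number of blocks containing each taxon of the universe.

    Taxa in the universe covered by no block get count 0.  For a thin
    r-uniform system covering its universe, some taxon has count at
    most r - 1 (a low-occurrence element always exists).
    """
    counts = {x: 0 for x in sorted(system.universe)}
    for b in system.blocks:
        for x in b:
            counts[x] += 1
    return counts


def has_sdr_after_deletion(
    system: SetSystem, B: Iterable[str]
) -> tuple[bool, dict | None]:
    """Decide whether {S - B : S in tau} has a system of distinct representatives.

    ``B`` must have size r - 1 for the uniform block size r.  The SDR
    question is solved as maximum bipartite matching (Hall's condition)
    between blocks and the taxa of their residual sets; on success the
    representative map ``block -> taxon`` is returned.  For a thin
    system the SDR is guaranteed to exist for every such B.
    """
    r = system.require_uniform()
    Bset = frozenset(B)
    if len(Bset) != r - 1:
        raise SetSystemError(f"deletion set must have size r-1={r - 1}, got {len(Bset)}")
    g = nx.Graph()
    block_nodes = []
    for i, s in enumerate(system.blocks):
        node = ("block", i)
        block_nodes.append(node)
        g.add_node(node, bipartite=0)
        for x in s - Bset:
            g.add_edge(node, ("taxon", x))
    matching = nx.bipartite.maximum_matching(g, top_nodes=block_nodes) if g.number_of_edges() else {}
    rep: dict = {}
    for i, s in enumerate(system.blocks):
        node = ("block", i)
        if node not in matching:
            return False, None
        rep[s] = matching[node][1]
    return True, rep


def zero_excess_family_is_patchwork(
    system: SetSystem, *, max_bruteforce: int = BRUTE_FORCE_CEILING
) -> bool:
    """Check the patchwork closure of the zero-excess sub-collections.

    For a slim system, the family P of non-empty sub-collections with
    exc' = 0 is closed under union and intersection of intersecting
    pairs (a *patchwork*); this follows from submodularity of the
    underlying coverage function.  Non-slim input raises, carrying the
    negative-excess witness.
    """
    ok, report = is_slim(system, method="brute", max_bruteforce=max_bruteforce)
    if not ok:
        raise SetSystemError(
            f"patchwork check requires a slim system; witness subset "
            f"{[sorted(b) for b in report.subset]} has exc' = {report.excess}"
        )
    zero: set[frozenset] = set()
    for comb in _iter_subsets(system.blocks):
        sub = [system.blocks[i] for i in comb]
        if excess_general(sub) == 0:
            zero.add(frozenset(sub))
    for A, B in itertools.combinations(zero, 2):
        if A & B:
            if (A & B) not in zero or (A | B) not in zero:
                return False
    return True
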