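"""Worked-example systems and seeded synthetic generators.

The catalog holds the small named instances used throughout the
package's documentation and tests: a four-block flexible/thin system
FIG1_TAU on six taxa, its non-thin extension FIG1_TAU_PRIME (adding
{b,d,e} drives the excess of the full collection to -1), the
five-triple incompatible assignment FIG1_COUNTEREXAMPLE_R witnessing
that failure, a thin system SEC1_TAU that no sequential
fresh-taxon ordering produces, the five-block FIG3_TAU with a known
caterpillar median representation, the pair-system examples for
total-order flexibility, and the extremal family {{1,2,j} : 2 < j <= n}
attaining the |tau| = n - 2 size bound.

The generators produce uniformly random set systems, guaranteed-thin
systems by sequential construction (each block introduces a fresh
taxon), and uniformly random rooted binary trees; all are reproducible
per seed.
"""

from __future__ import annotations

import math
import random
from typing import Iterable, Sequence

from . import set_systems
from .set_systems import SetSystem, SetSystemError
from .trees import RootedTree, TripleSet

__all__ = [
    "FIG1_TAU",
    "FIG1_TAU_PRIME",
    "FIG1_COUNTEREXAMPLE_R",
    "SEC1_TAU",
    "FIG3_TAU",
    "ORDER_FLEX_PAIR",
    "ORDER_RIGID_TRIANGLE",
    "prop1_family",
    "random_set_system",
    "random_thin_system",
    "random_rooted_binary_tree",
]

#: Four size-3 blocks on {a..f}: thin, hence phylogenetically flexible.
FIG1_TAU = SetSystem([{"a", "b", "c"}, {"a", "b", "d"}, {"b", "c", "e"}, {"d", "e", "f"}])

#: FIG1_TAU plus {b,d,e}: the full five-block collection has excess -1.
FIG1_TAU_PRIME = SetSystem(
    [{"a", "b", "c"}, {"a", "b", "d"}, {"b", "c", "e"}, {"d", "e", "f"}, {"b", "d", "e"}]
)

#: An incompatible assignment of one triple per block of FIG1_TAU_PRIME.
FIG1_COUNTEREXAMPLE_R = TripleSet(["a,b|c", "b,d|a", "b,c|e", "d,f|e", "b,e|d"])

#: Thin, but unreachable by any fresh-taxon sequential ordering.
SEC1_TAU = SetSystem([{"a", "b", "c"}, {"c", "d", "e"}, {"b", "e", "f"}, {"a", "d", "f"}])

#: Five blocks on seven taxa with a caterpillar median representation.
FIG3_TAU = SetSystem(
    [{"a", "b", "c"}, {"c", "d", "e"}, {"a", "e", "f"}, {"b", "e", "g"}, {"a", "d", "g"}]
)

#: The two-pair system that is total-order flexible ...
ORDER_FLEX_PAIR = SetSystem([{"a", "b"}, {"b", "c"}])

#: ... and the triangle that is not (a<b, b<c, c<a has no extension).
ORDER_RIGID_TRIANGLE = SetSystem([{"a", "b"}, {"b", "c"}, {"a", "c"}])


def prop1_family(n: int) -> SetSystem:
    """The extremal thin family {{1,2,j} : 2 < j <= n} of size n - 2,
    attaining the flexible-size bound |tau| = |X| - 2 with equality."""
    if n < 3:
        raise SetSystemError(f"family needs n >= 3, got {n}")
    return SetSystem([{"1", "2", str(j)} for j in range(3, n + 1)])


def _letters(n: int) -> list[str]:
    if n <= 26:
        return [chr(ord("a") + i) for i in range(n)]
    return [f"x{i + 1}" for i in range(n)]


def random_set_system(
    n_taxa: int, n_blocks: int, block_size: int, seed: int
) -> SetSystem:
    """Uniform sample of ``n_blocks`` distinct size-``block_size``
    subsets of an ``n_taxa`` universe; reproducible per seed."""
    total = math.comb(n_taxa, block_size)
    if n_blocks > total:
        raise SetSystemError(
            f"cannot draw {n_blocks} distinct blocks of size {block_size} "
            f"from {n_taxa} taxa (only {total} exist)"
        )
    rng = random.Random(seed)
    taxa = _letters(n_taxa)
    blocks: set = set()
    while len(blocks) < n_blocks:
        blocks.add(frozenset(rng.sample(taxa, block_size)))
    return SetSystem(blocks, universe=taxa)


def random_thin_system(n_blocks: int, block_size: int, seed: int) -> SetSystem:
    """A thin system by sequential construction: every block after the
    first contains at least one taxon absent from all earlier blocks,
    which forces each sub-collection's excess to stay non-negative.
    Not every thin system arises this way (see SEC1_TAU).  The output
    is re-verified thin before being returned."""
    if block_size < 2:
        raise SetSystemError("block size must be >= 2")
    if n_blocks < 1:
        raise SetSystemError("need at least one block")
    rng = random.Random(seed)
    pool: list[str] = []
    fresh = 0

    def new_taxon() -> str:
        nonlocal fresh
        fresh += 1
        return f"t{fresh}"

    blocks: list[frozenset] = []
    for i in range(n_blocks):
        lo = max(1, block_size - len(pool))
        n_new = rng.randint(lo, block_size)
        old = rng.sample(pool, block_size - n_new)
        new = [new_taxon() for _ in range(n_new)]
        blocks.append(frozenset(old + new))
        pool.extend(new)
    system = SetSystem(blocks)
    ok, _ = set_systems.is_thin(system)
    assert ok, "sequential construction must yield a thin system"
    return system


def random_rooted_binary_tree(taxa: Iterable[str], seed: int) -> RootedTree:
    """A uniformly random rooted binary tree on the given taxa.

    Taxa are inserted in sorted order, each attached uniformly at
    random above one of the 2k - 1 existing subtrees (including the
    whole tree); as (2n-3)!! = prod(2k - 1), every shape is produced
    with equal probability."""
    labels = sorted(frozenset(taxa))
    if len(labels) < 2:
        raise SetSystemError("need at least 2 taxa")
    rng = random.Random(seed)

    def count_nodes(shape) -> int:
        if isinstance(shape, str):
            return 1
        return 1 + count_nodes(shape[0]) + count_nodes(shape[1])

    from itertools import islice

    from .trees import _insert_everywhere

    shape = labels[0]
    for x in labels[1:]:
        k = rng.randrange(count_nodes(shape))  # 2j-1 positions at step j
        shape = next(islice(_insert_everywhere(shape, x), k, None))
    return RootedTree.from_nested(shape)
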