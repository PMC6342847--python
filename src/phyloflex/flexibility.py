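"""Phylogenetic flexibility deciders.

A set system tau is *phylogenetically flexible* when every assignment
of one rooted (binary) tree per block yields a compatible collection —
i.e. the taxon-coverage pattern alone guarantees that the BUILD
supertree method succeeds no matter which trees are supplied.  Two
exact characterisations make this decidable without enumeration:

* size-3 blocks: flexible iff the system is thin;
* blocks of size >= 3: flexible iff the system is slim.

This module embodies those equivalences as cross-validated deciders:
an exhaustive route (enumerate every assignment and run BUILD on each)
and the criterion route (thin/slim via :mod:`phyloflex.set_systems`),
with ``method="both"`` insisting the two agree.  It also carries the
heredity check, the |tau| <= n - 2 size bound for flexible systems,
and the display-multiplicity floor for the extremal family
{{1,2,j} : 2 < j <= n}.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from . import set_systems, trees
from .set_systems import CapacityError, SetSystem, SetSystemError
from .trees import RootedTree, RootedTriple, TripleSet

__all__ = [
    "AssignmentReport",
    "is_flexible_triples",
    "is_flexible_general",
    "flexibility_is_hereditary_check",
    "flexible_size_bound_check",
    "multiplicity_floor_check",
    "triples_on_block",
    "EXHAUSTIVE_TRIPLES_CEILING",
    "EXHAUSTIVE_SHAPES_CEILING",
]

# Exhaustive assignment enumeration caps (overridable per call).
EXHAUSTIVE_TRIPLES_CEILING = 12        # 3^12 assignments
EXHAUSTIVE_SHAPES_CEILING = 10 ** 6    # product of per-block shape counts


@dataclass(frozen=True)
class AssignmentReport:
    """Outcome of a flexibility decision.

    ``counterexample`` is a tuple of rooted trees/triples (one per
    block, in canonical block order) witnessing an incompatible
    assignment; present exactly when the system is not flexible and an
    exhaustive search ran.  ``compatible_assignments`` is None when the
    search short-circuited or only the criterion route ran.
    """

    flexible: bool
    total_assignments: int
    compatible_assignments: int | None
    counterexample: tuple | None


def triples_on_block(block) -> tuple[RootedTriple, ...]:
    """The three rooted triples on a size-3 block, in canonical order."""
    a, b, c = sorted(block)
    return (RootedTriple(a, b, c), RootedTriple(a, c, b), RootedTriple(b, c, a))


def _exhaustive_triples(
    system: SetSystem, count: bool
) -> AssignmentReport:
    choices = [triples_on_block(b) for b in system.blocks]
    total = 3 ** len(system)
    compatible = 0
    counterexample = None
    for assignment in itertools.product(*choices):
        tuples = [t.as_tuple() for t in assignment]
        if trees._compatible_tuples(tuples) is not None:
            compatible += 1
        else:
            if counterexample is None:
                counterexample = tuple(assignment)
            if not count:
                return AssignmentReport(
                    flexible=False,
                    total_assignments=total,
                    compatible_assignments=None,
                    counterexample=counterexample,
                )
    return AssignmentReport(
        flexible=compatible == total,
        total_assignments=total,
        compatible_assignments=compatible,
        counterexample=counterexample,
    )


def is_flexible_triples(
    system: SetSystem,
    method: str = "exhaustive",
    *,
    count: bool = True,
    max_blocks: int = EXHAUSTIVE_TRIPLES_CEILING,
) -> AssignmentReport:
    """Decide flexibility of a uniform size-3 system.

    ``method="exhaustive"`` enumerates all 3^|tau| triple assignments
    and runs BUILD on each; ``"thin"`` applies the excess criterion;
    ``"both"`` runs both and raises on disagreement.  With
    ``count=False`` the exhaustive search stops at the first
    incompatible assignment.
    """
    if system.require_uniform() != 3:
        raise set_systems.UniformityError(
            "triple flexibility requires uniform block size 3"
        )
    if method in ("exhaustive", "both"):
        if len(system) > max_blocks:
            raise CapacityError(
                f"exhaustive search over 3^{len(system)} assignments exceeds "
                f"cap 3^{max_blocks}"
            )
        report = _exhaustive_triples(system, count)
        if method == "both":
            thin, _ = set_systems.is_thin(system)
            if thin != report.flexible:
                raise AssertionError(
                    f"thin criterion ({thin}) disagrees with exhaustive "
                    f"flexibility ({report.flexible})"
                )
        return report
    if method == "thin":
        thin, _ = set_systems.is_thin(system)
        return AssignmentReport(
            flexible=thin,
            total_assignments=3 ** len(system),
            compatible_assignments=None,
            counterexample=None,
        )
    raise ValueError(f"unknown method: {method!r}")


def _exhaustive_general(system: SetSystem, count: bool, cap: int) -> AssignmentReport:
    per_block: list[list] = []
    total = 1
    for b in system.blocks:
        labels = tuple(sorted(b))
        shapes = [shape for shape, _ in trees._tree_triple_index(labels)]
        per_block.append(labels)
        total *= len(shapes)
    if total > cap:
        raise CapacityError(
            f"exhaustive search over {total} tree assignments exceeds cap {cap}"
        )
    indexed = [trees._tree_triple_index(tuple(sorted(b))) for b in system.blocks]
    compatible = 0
    counterexample = None
    for assignment in itertools.product(*indexed):
        tuples = [t for _shape, trips in assignment for t in trips]
        if trees._compatible_tuples(tuples) is not None:
            compatible += 1
        else:
            if counterexample is None:
                counterexample = tuple(
                    RootedTree.from_nested(shape) for shape, _ in assignment
                )
            if not count:
                return AssignmentReport(
                    flexible=False,
                    total_assignments=total,
                    compatible_assignments=None,
                    counterexample=counterexample,
                )
    return AssignmentReport(
        flexible=compatible == total,
        total_assignments=total,
        compatible_assignments=compatible,
        counterexample=counterexample,
    )


def is_flexible_general(
    system: SetSystem,
    method: str = "exhaustive",
    *,
    count: bool = True,
    max_assignments: int = EXHAUSTIVE_SHAPES_CEILING,
) -> AssignmentReport:
    """Decide flexibility for blocks of size >= 3 (mixed sizes allowed).

    ``method="exhaustive"`` assigns every rooted binary tree shape to
    every block ((2|s|-3)!! shapes each), reducing compatibility of a
    tree collection to triple compatibility of the union of induced
    triples; ``"slim"`` applies the exc' criterion; ``"both"``
    cross-validates.
    """
    for b in system.blocks:
        if len(b) < 3:
            raise set_systems.BlockSizeError(
                f"general flexibility requires blocks of size >= 3, got {sorted(b)}"
            )
    if method in ("exhaustive", "both"):
        report = _exhaustive_general(system, count, max_assignments)
        if method == "both":
            slim, _ = set_systems.is_slim(system)
            if slim != report.flexible:
                raise AssertionError(
                    f"slim criterion ({slim}) disagrees with exhaustive "
                    f"flexibility ({report.flexible})"
                )
        return report
    if method == "slim":
        slim, _ = set_systems.is_slim(system)
        total = 1
        for b in system.blocks:
            total *= trees.double_factorial(2 * len(b) - 3)
        return AssignmentReport(
            flexible=slim,
            total_assignments=total,
            compatible_assignments=None,
            counterexample=None,
        )
    raise ValueError(f"unknown method: {method!r}")


def flexibility_is_hereditary_check(system: SetSystem) -> bool:
    """Verify that every non-empty sub-collection of a flexible system
    is itself flexible (heredity).  Exhaustive-capacity scale only."""
    full = is_flexible_triples(system, method="exhaustive", count=False)
    if not full.flexible:
        raise SetSystemError("heredity check expects a flexible system")
    for k in range(1, len(system) + 1):
        for comb in itertools.combinations(system.blocks, k):
            sub = system.restrict(comb)
            if not is_flexible_triples(sub, method="exhaustive", count=False).flexible:
                return False
    return True


def flexible_size_bound_check(system: SetSystem) -> bool:
    """For a flexible size-3 system covering its universe, |tau| <= n - 2.

    Returns the truth of the bound for flexible input; vacuously true
    for non-flexible input.
    """
    if system.require_uniform() != 3:
        raise set_systems.UniformityError("size bound applies to size-3 systems")
    if system.leaves != system.universe:
        raise SetSystemError("size bound assumes the system covers its universe")
    flexible, _ = set_systems.is_thin(system)
    if not flexible:
        return True
    return len(system) <= len(system.universe) - 2


def multiplicity_floor_check(
    system: SetSystem, *, max_taxa: int = 7
) -> bool:
    """Is every triple assignment displayed by at least two trees?

    For the extremal flexible family {{1,2,j} : 2 < j <= n} with
    n >= 6 every assignment is displayed by more than one rooted
    binary tree; a single block (unique display) fails the floor.
    Decided purely by enumeration over all (2n-3)!! trees; refused
    above ``max_taxa`` leaves.
    """
    if system.require_uniform() != 3:
        raise set_systems.UniformityError("multiplicity floor applies to size-3 systems")
    X = tuple(sorted(system.leaves))
    if len(X) > max_taxa:
        raise CapacityError(f"tree enumeration over {len(X)} taxa exceeds cap {max_taxa}")
    index = trees._tree_triple_index(X)
    choices = [triples_on_block(b) for b in system.blocks]
    for assignment in itertools.product(*choices):
        need = frozenset(t.as_tuple() for t in assignment)
        hits = 0
        for _shape, trips in index:
            if need <= trips:
                hits += 1
                if hits >= 2:
                    break
        if hits < 2:
            return False
    return True
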