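# Methods

This note records the model the package implements, the algorithmic
choices behind each decider, the defaults that matter, and what the
synthetic generators do and do not emulate.

## Objects and conventions

A `SetSystem` is a collection of pairwise-distinct blocks (taxon
subsets, each of size ≥ 2) over a universe X that defaults to the leaf
union L(τ). Taxon labels are totally ordered strings free of
whitespace and `,|();`, which fixes a canonical order on blocks
(sorted member tuples) and hence deterministic witnesses and
serialisations throughout. Duplicate blocks are rejected at
construction (τ is a set of sets); a `dedupe=True` escape hatch drops
them with a warning. Blocks of size 2 are legal in the model — the
pair-system theory needs them — but every slim-related operation
(exc′, γ, `is_slim`, patchwork) rejects them, since exc′ is defined
only for blocks of size ≥ 3. Mixed block sizes are likewise rejected
by the uniform-excess operations rather than silently coerced: there
is no accepted convention for exc on mixed sizes, so the package
refuses to guess.

Excess functions require non-empty sub-collections; the coverage
functions σ and γ extend to the empty set with value 0 (their
summation terms are empty), which is what makes the submodularity
inequality well-formed for disjoint arguments.

## Deciders and their two routes

`is_thin` / `is_slim` each run in one of two modes, cross-validated in
the test suite:

* **brute** — enumerate all 2^|τ|−1 non-empty sub-collections in
  (size, lexicographic) order and minimise the excess. The first
  minimiser encountered in that order is the canonical witness, so
  ties break deterministically toward smaller, lexicographically
  earlier subsets. Enumeration is refused above 20 blocks unless the
  cap is raised explicitly.
* **poly** — threshold the submodular minimum: thin ⟺ σ* ≥ r − 1,
  slim ⟺ γ* ≥ 2. The classical statement of the σ* criterion is for
  r ≥ 3 (threshold 2); the identity exc = σ − (r − 1) on non-empty
  sub-collections gives the same test at every uniform size, and the
  package uses the general threshold so pair systems ride the same
  code path.

`auto` picks brute up to 15 blocks and poly beyond. The verdicts are
exercised against each other on hundreds of seeded systems; the
*witness subsets* of the two routes may legitimately differ when the
minimum is attained more than once (the min-cut argmin is whatever the
cut structure yields, re-validated by recomputation, while brute
returns the canonical minimiser). Reporting an argmin at all is an
extension of the σ*/γ* definition, which only fixes the value.

## Submodular minimisation by forced-element min-cut

σ(τ′) = |L(τ′)| − |τ′| and γ(τ′) = |L(τ′)| − Σ(|s| − 2) are submodular
(checkable via `check_submodularity`, exhaustively for ≤ 8 blocks).
Generic polynomial submodular minimisation (ellipsoid-based) is
impractical; because σ and γ are coverage-type, their minima reduce to
max-flow. For each forced block s build the network

    source → block_i   capacity w_i  (∞ for i = s)
    block_i → taxon x  capacity ∞    (when x ∈ block_i)
    taxon x → sink     capacity 1

with w_i = 1 for σ and |s_i| − 2 for γ. Any finite cut keeps a block
set Y ∋ s on the source side and must cut the unit edges of every
taxon they cover, so cut = Σw − w(Y) + |N(Y)| and

    min_{Y ∋ s} (|N(Y)| − w(Y)) = mincut − Σw.

Minimising over the forced element gives σ*/γ* exactly; the argmin is
read off the source side of the cut. "Infinite" capacity is realised
as Σ weights + Σ degrees + 1, strictly larger than any finite cut.
Flow is solved by networkx's `minimum_cut`; the construction is
validated against subset enumeration on 200 seeded systems in the
acceptance suite. The published surplus algorithm of Fritzilas et al.
is not re-implemented; the min-cut route plus the brute-force oracle
covers the same contract (`graph_surplus`, and the degree-2-forest
characterisation of positive surplus as a small brute-force test
utility capped at 20 containment edges).

## BUILD and the cluster graph

Compatibility of rooted triples is decided by the Aho BUILD recursion:
partition the current taxon set S by connected components of the
cluster graph [R, S] (edge {a,b} for each triple ab|c with all three
leaves in S); a single component with |S| ≥ 2 means incompatible;
otherwise recurse per component. Components are computed with a small
union-find on the current label set — the recursion is the inner loop
of the exhaustive flexibility sweeps (tens of thousands of calls), and
per-call graph-object construction would dominate the runtime; the
equivalence with the all-S disconnectedness criterion is asserted
exhaustively on random instances in the tests. Children are ordered by
smallest descendant leaf, so the BUILD tree is canonical. The tree is
in general non-binary; `refine_binary` resolves each multifurcation as
a left-leaning caterpillar over children in that same order, which
preserves everything the tree displays.

Exhaustive oracles enumerate rooted binary shapes by sequential leaf
insertion in sorted taxon order (each new taxon into every edge plus a
new root position), yielding each of the (2n−3)!! shapes exactly once
in a reproducible order; enumeration is refused above 9 leaves.
Display counting caches, per taxon set, every shape with its displayed
triple set, so sweeps over assignments are set-containment tests.

## Flexibility sweeps

`is_flexible_triples` enumerates the 3^|τ| assignments (cap 3¹²) and
runs BUILD on each; `is_flexible_general` assigns every rooted binary
shape per block (cap 10⁶ assignments), reducing tree-collection
compatibility to triple compatibility via the display equivalence
(a tree displays a binary tree iff it displays all its triples).
When only the verdict is wanted (`count=False`) the sweep
short-circuits at the first incompatible assignment and reports it as
the counterexample; in counting mode the full census is taken and
`flexible ⟺ compatible = total` holds by construction. `method="both"`
raises on any disagreement between sweep and criterion, which is how
the equivalence theorems are exercised as executable checks.

## Caterpillar constructions

**Median (size-3 blocks, |X| ≥ 4).** A caterpillar on X is encoded as
a leaf ordering: positions 1–2 and n−1–n form the end cherries and the
median of a block is the spine vertex of its *middle* leaf, so median
injectivity is a constant-time test per block on the ordering. The
construction follows the inductive proof strategy: find a taxon x in
at most two blocks (guaranteed for thin covering systems); if one
block, drop it, solve the reduced system, and re-insert x; if two
blocks t, t′, replace them by a merged 3-block drawn from (t∪t′)−{x}
(candidates keep a full pair from one of the two blocks; those that
break thinness are skipped), solve, and re-insert. Rather than
tracking the proof's subcase geometry — whose published case labels
are internally inconsistent and contain an apparent typo in one
distance comparison — every re-insertion position on the spine is
tried and checked against the injectivity postcondition, with
backtracking across candidate merges; existence of a working position
is exactly what the induction guarantees. If the recursion fails
anyway, a bounded exhaustive search over leaf orderings (≤ 10 taxa,
reversal symmetry halved) is the fallback; correctness is defined by
the verified postcondition, not the proof's letter. Universe taxa
outside L(τ) are appended beyond the last interior vertex, where no
block median can land. The output is always re-verified (caterpillar
predicate + injectivity) before being returned.

**lca (size-2 blocks, L(τ) = X).** Peel a taxon x contained in exactly
one pair {a,x}; the reduced system loses either x alone or both x and
a; re-attach above the recursive caterpillar's root (one new cherry
level, or two when a was also lost). Each new lca is the new root, so
injectivity is preserved; the result is re-verified. With a fresh leaf
attached above the root, the rooted caterpillar read as an unrooted
tree turns the lca map into the median map of the x-augmented blocks —
the round trip asserted in the tests.

**Deterministic choices**: smallest-label taxon among equal-occurrence
candidates, canonical block order among qualifying block pairs,
first verified insertion position. These fix the output tree for a
given input.

## Pair systems

Total-order flexibility is decided by orienting each pair and testing
the orientation digraph for acyclicity (Kahn's algorithm): an acyclic
orientation extends to a total order by topological sorting, a cyclic
one witnesses rigidity and is returned. Exhaustive enumeration over
2^|τ| orientations is capped at 20 blocks; the thin criterion covers
larger systems. The forest criterion builds the bipartite containment
graph G(τ) and applies networkx's forest test. The three pair-system
deciders (thin, forest, total order) are asserted equal on all 1023
pair systems over five taxa.

## Synthetic generators

`random_set_system(n_taxa, n_blocks, block_size, seed)` samples
distinct blocks uniformly without replacement. At the scale used for
the equivalence sweeps (6–7 taxa, up to 5 size-3 blocks) both thin and
non-thin outcomes occur with substantial frequency, so the seeded
sweeps exercise both directions of every equivalence; the tests assert
this mix rather than assume it.

`random_thin_system(n_blocks, block_size, seed)` builds a
guaranteed-thin system sequentially: each block after the first draws
at least one fresh taxon, which keeps every sub-collection's excess
non-negative. Not every thin system is reachable this way — the
catalog's four-block example on {a..f} provably admits no such
ordering, and the tests verify that — so property tests over this
generator cover a (large) subclass of thin systems; the catalog
fixtures and the rejection-sampled slim systems cover the rest.

`random_rooted_binary_tree(taxa, seed)` inserts taxa in sorted order,
each uniformly over the 2k−1 attachment positions; since
(2n−3)!! = Π(2k−1), the distribution over labelled shapes is exactly
uniform (chi-square-style frequency checks at n = 3, 4 in the tests).

The generators produce abstract coverage patterns; they do not emulate
gene-sampling biases, correlated taxon dropout, or the block-size
distributions of real phylogenomic matrices. Passing equivalence
sweeps therefore establishes the combinatorial correctness of the
deciders on the tested regime, not any distributional claim about
empirical coverage patterns.

## Capacities and problem sizes

All enumeration caps are explicit, overridable arguments: 20 blocks
for subset enumeration (auto-switch to poly at 15), 3¹² assignments
for triple sweeps, 10⁶ for general tree-assignment sweeps, 9 leaves
for tree enumeration, 10 taxa for the ordering fallback, 20 edges for
the degree-2-forest search, 20 blocks for orientation sweeps. The
seeded test batches (200 uniform systems on ≤ 7 taxa, 50 mixed-size
systems, 100 thin systems on ≤ 10 taxa, 200 minimisation instances)
were sized so the full suite exercises every equivalence at exhaustive
strength while remaining a desk-scale computation; the theorems being
checked are exact, so instance count buys confidence in the
implementation, not in the mathematics.

## Known limitations

* Incompatibility is reported with a witness, never "resolved": no
  heuristic supertree method (MinCut, MRP) is included by design.
* Median representations are only constructed for size-3 blocks; the
  known extension to larger blocks is out of scope.
* The min-cut minimiser is specific to the coverage functions σ and γ;
  it is not a general submodular minimiser.
* `ExcessReport` witnesses from the poly route depend on networkx's
  cut structure; only their values (not identities) are canonical.
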