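# phyloflex

**Phylogenetic flexibility of taxon-coverage patterns: thin/slim
criteria, BUILD supertrees, caterpillar representations, and
submodular min-cut deciders.**

## The problem

In phylogenomics, trees are routinely estimated on different, partially
overlapping subsets of species — each gene has been sequenced only for
some taxa — and then combined into a supertree. Supertree methods such
as the BUILD algorithm of Aho et al. require the input trees to be
*compatible* (displayable by one parent tree), and whether that can
fail depends on the pattern of taxon coverage. A collection
τ = {s₁, …, sₖ} of taxon subsets is **phylogenetically flexible** when
*every* assignment of a rooted tree to each leaf set sᵢ yields a
compatible collection: for such coverage patterns the supertree step
can never fail — and, by the same token, observed compatibility
carries no evidence about the accuracy of the input trees.

`phyloflex` decides flexibility exactly and constructs the associated
certificates, for anyone analysing taxon-coverage patterns: a
supertree when the triples are compatible, an incompatible assignment
when the pattern is not flexible, and caterpillar median/lca
representations certifying the sparsity condition.

## The criteria

For a sub-collection τ′ write L(τ′) for the union of its blocks. With
uniform block size r, the **excess** is

    exc(τ′) = |L(τ′)| − |τ′| − (r − 1),

and τ is **thin** when every non-empty τ′ ⊆ τ has exc(τ′) ≥ 0. For
mixed block sizes ≥ 3 the analogue is

    exc′(τ′) = |L(τ′)| − 2 − Σ_{s∈τ′} (|s| − 2),

and τ is **slim** when exc′ ≥ 0 throughout. The central equivalences:

* size-3 blocks: τ is phylogenetically flexible **iff** τ is thin;
* blocks of size ≥ 3: τ is flexible **iff** τ is slim;
* size-2 blocks: τ is thin **iff** τ is *total-order flexible* (every
  orientation of the pairs extends to a total order) **iff** the
  block/taxon incidence graph G(τ) is a forest.

Thinness of a size-3 system is further equivalent to the existence of
an unrooted *caterpillar* tree whose median map s ↦ med_T(s) is
injective on τ; `phyloflex` builds one. Because the coverage functions
σ(τ′) = |L(τ′)| − |τ′| and γ(τ′) = |L(τ′)| − Σ(|s| − 2) are
submodular, the minima σ* and γ* over non-empty sub-collections are
computable in polynomial time — here by a forced-element min-cut
construction on G(τ) — giving scalable deciders: thin ⟺ σ* ≥ r − 1,
slim ⟺ γ* ≥ 2.

## Worked example

The four-block collection τ = {{a,b,c}, {a,b,d}, {b,c,e}, {d,e,f}} on
six taxa, as a text file (one block per line):

```
$ cat fig1.txt
a,b,c
a,b,d
b,c,e
d,e,f

$ phyloflex check-thin fig1.txt
thin: True (min excess 0 on {['a', 'b', 'c']})

$ phyloflex check-flexible fig1.txt --method exhaustive --count
flexible: True (81/81 assignments compatible)
```

All 3⁴ = 81 ways of resolving each block into a rooted triple are
compatible: the coverage pattern alone guarantees a supertree. The
certifying caterpillar (medians of the four blocks land on four
distinct interior vertices):

```
$ phyloflex median-caterpillar fig1.txt
[&U] (a,(b,(c,e)),(d,f));
```

Adding the block {b,d,e} destroys the property — the five-block
collection now has negative excess (5 blocks but the relevant
sub-collections cover too few taxa):

```
$ phyloflex check-thin fig1p.txt
thin: False (min excess -1 on {['a', 'b', 'c'], ['a', 'b', 'd'], ['b', 'c', 'e'], ['b', 'd', 'e']})

$ phyloflex check-flexible fig1p.txt --method exhaustive --count
flexible: False (153/243 assignments compatible)
counterexample assignment: a,b|c, a,d|b, b,c|e, b,e|d, d,e|f
```

90 of the 243 assignments — the printed one among them — admit no
supertree on the six taxa. Exit codes follow the verdict (0 holds,
1 fails with a witness, 2 usage/parse error); `--json` emits a
machine-readable run report. Other subcommands: `check-slim`,
`build-supertree`, `order-flexible`, `count-trees`, `generate`.

The same operations are available as a library:

```python
from phyloflex import SetSystem, is_thin, is_flexible_triples, sigma_star

tau = SetSystem([{"a","b","c"}, {"a","b","d"}, {"b","c","e"}, {"d","e","f"}])
is_thin(tau)                      # (True, ExcessReport(..., excess=0, ...))
sigma_star(tau).value             # 2  (>= 2: thin via the min-cut route)
is_flexible_triples(tau).compatible_assignments  # 81
```

## Layout

- `set_systems.py` — data model, excess functions, brute-force
  thin/slim deciders with witnesses, SDR via bipartite matching,
  patchwork closure of zero-excess families
- `trees.py` — rooted trees and triples, display relations, cluster
  graphs, BUILD, exhaustive tree enumeration and display counting
- `flexibility.py` — exhaustive and criterion-based flexibility
  deciders, heredity/size-bound/multiplicity checks
- `submodular.py` — σ/γ, submodularity check, forced-element min-cut
  minimisation of σ*/γ*, bipartite surplus utilities
- `representations.py` — caterpillar median and lca constructions,
  forest criterion, total-order flexibility
- `fixtures.py` — worked-example catalog and seeded generators
- `io.py`, `cli.py` — file formats and the `phyloflex` command

See `docs/methods.md` for the algorithms, parameter defaults and
design decisions.
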