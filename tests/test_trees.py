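"""Triples, display relations, BUILD, enumeration oracles, counting."""

import itertools
import random

import networkx as nx
import pytest

from phyloflex import (
    CapacityError,
    RootedTree,
    RootedTriple,
    SetSystemError,
    TripleSet,
    cluster_graph,
    count_displaying_trees,
    disjoint_display_count,
    displays_tree,
    displays_triple,
    enumerate_rooted_binary_trees,
    induced_triples,
    is_compatible,
    refine_binary,
    unique_defining_triples,
)
from phyloflex import fixtures as fx
from phyloflex.trees import double_factorial


def T(nested):
    return RootedTree.from_nested(nested)


class TestTriples:
    def test_canonical_form_and_parse(self):
        t = RootedTriple("b", "a", "c")
        assert t.cherry == ("a", "b") and t.outgroup == "c"
        assert str(t) == "a,b|c"
        assert RootedTriple.parse("b,a|c") == t
        assert RootedTriple.parse("ab|c") == t  # single-char shorthand

    def test_distinct_labels_required(self):
        with pytest.raises(SetSystemError):
            RootedTriple("a", "a", "b")

    def test_tripleset_support(self):
        R = fx.FIG1_COUNTEREXAMPLE_R
        assert R.leaves == frozenset("abcdef")
        assert R.support == frozenset(b for b in fx.FIG1_TAU_PRIME.blocks)


class TestDisplay:
    def test_three_leaf_tree(self):
        tree = T((("a", "b"), "c"))
        assert displays_triple(tree, RootedTriple("a", "b", "c"))
        assert not displays_triple(tree, RootedTriple("a", "c", "b"))
        assert not displays_triple(tree, RootedTriple("b", "c", "a"))

    def test_caterpillar_displays(self):
        tree = T(((("a", "b"), "c"), "d"))
        assert displays_triple(tree, RootedTriple("b", "c", "d"))
        assert not displays_triple(tree, RootedTriple("c", "d", "a"))

    def test_missing_label(self):
        with pytest.raises(SetSystemError):
            displays_triple(T((("a", "b"), "c")), RootedTriple("a", "b", "z"))

    def test_induced_triples(self):
        assert induced_triples(T((("a", "b"), "c"))) == TripleSet(["a,b|c"])
        star = RootedTree.from_nested(("a", "b", "c"))
        assert induced_triples(star) == TripleSet()
        got = induced_triples(T(((("a", "b"), "c"), "d")))
        assert got == TripleSet(["a,b|c", "a,b|d", "a,c|d", "b,c|d"])

    def test_binary_tree_one_triple_per_3subset(self):
        for seed in range(5):
            tree = fx.random_rooted_binary_tree("abcdef", seed)
            trips = induced_triples(tree)
            supports = [t.labels for t in trips]
            assert len(trips) == 20 and len(set(supports)) == 20

    def test_displays_tree(self):
        parent = T(((("a", "b"), "c"), "d"))
        assert displays_tree(parent, parent)
        assert displays_tree(parent, T((("a", "b"), "c")))
        assert not displays_tree(T((("a", "c"), ("b", "d"))), T((("a", "b"), "c")))

    def test_displays_tree_leafset_guard(self):
        with pytest.raises(SetSystemError):
            displays_tree(T((("a", "b"), "c")), T((("a", "b"), "z")))


class TestClusterGraph:
    def test_counterexample_connected(self):
        g = cluster_graph(fx.FIG1_COUNTEREXAMPLE_R, "abcdef")
        assert nx.is_connected(g)

    def test_triples_outside_S_excluded(self):
        g = cluster_graph([RootedTriple("a", "b", "c")], {"a", "b"})
        assert g.number_of_edges() == 0 and set(g) == {"a", "b"}
        g = cluster_graph([RootedTriple("a", "b", "c")], {"a", "b", "c"})
        assert set(g.edges()) == {("a", "b")}

    def test_lemma3_two_components(self):
        # one triple supporting each interior non-root vertex of a binary
        # tree => the cluster graph on X has exactly two components
        rng = random.Random(4)
        for seed in range(10):
            tree = fx.random_rooted_binary_tree("abcdef", seed)
            below = tree.node_leafset()
            R = []
            for node in tree.preorder():
                if node.is_leaf or node.parent is None:
                    continue
                k1, k2 = node.children
                x = rng.choice(sorted(below[k1]))
                y = rng.choice(sorted(below[k2]))
                z = rng.choice(sorted(tree.leaf_labels - below[node]))
                R.append(RootedTriple(x, y, z))
            g = cluster_graph(R, tree.leaf_labels)
            assert nx.number_connected_components(g) == 2


def _bryant_steel_compatible(R):
    """Direct criterion: [R, S] disconnected for every S with |S| >= 2."""
    X = sorted(TripleSet(R).leaves)
    for k in range(2, len(X) + 1):
        for S in itertools.combinations(X, k):
            if nx.is_connected(cluster_graph(R, S)):
                return False
    return True


class TestBuild:
    def test_counterexample_incompatible(self):
        ok, tree = is_compatible(fx.FIG1_COUNTEREXAMPLE_R)
        assert not ok and tree is None

    def test_single_triple(self):
        ok, tree = is_compatible([RootedTriple("a", "b", "c")])
        assert ok and tree == T((("a", "b"), "c"))

    def test_cluster_from_two_triples(self):
        R = [RootedTriple("a", "b", "c"), RootedTriple("a", "b", "d")]
        ok, tree = is_compatible(R)
        assert ok and frozenset("ab") in tree.clusters()
        assert all(displays_triple(tree, r) for r in R)
        # oracle: every displaying tree among all 15 on {a,b,c,d} has the
        # cherry cluster {a,b} forced by the two triples
        displaying = [
            t
            for t in enumerate_rooted_binary_trees("abcd")
            if all(displays_triple(t, r) for r in R)
        ]
        assert displaying
        assert all(frozenset("ab") in t.clusters() for t in displaying)

    def test_empty_compatible(self):
        ok, tree = is_compatible([])
        assert ok and tree is None

    def test_conflicting_triples_on_same_support(self):
        ok, _ = is_compatible([RootedTriple("a", "b", "c"), RootedTriple("a", "c", "b")])
        assert not ok

    def test_build_tree_displays_input(self):
        rng = random.Random(17)
        for _ in range(40):
            X = "abcdef"[: rng.randint(4, 6)]
            R = [
                RootedTriple(*rng.sample(X, 3))
                for _ in range(rng.randint(1, 5))
            ]
            ok, tree = is_compatible(R)
            if ok:
                assert all(displays_triple(tree, t) for t in R)

    def test_agrees_with_bryant_steel_criterion(self):
        rng = random.Random(23)
        seen_incompatible = 0
        for _ in range(60):
            X = "abcdefg"[: rng.randint(4, 6)]
            R = [RootedTriple(*rng.sample(X, 3)) for _ in range(rng.randint(1, 5))]
            ok, _ = is_compatible(R)
            assert ok == _bryant_steel_compatible(R)
            seen_incompatible += not ok
        assert seen_incompatible > 0

    def test_refine_binary(self):
        ok, tree = is_compatible(
            [RootedTriple("a", "b", "e"), RootedTriple("c", "d", "e")]
        )
        assert ok
        ref = refine_binary(tree)
        assert ref.is_binary
        assert displays_tree(ref, ref) and all(
            displays_triple(ref, t)
            for t in [RootedTriple("a", "b", "e"), RootedTriple("c", "d", "e")]
        )


class TestEnumeration:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7])
    def test_counts_match_double_factorial(self, n):
        labels = "abcdefg"[:n]
        trees = list(enumerate_rooted_binary_trees(labels))
        assert len(trees) == double_factorial(2 * n - 3)

    def test_trees_pairwise_distinct(self):
        trees = list(enumerate_rooted_binary_trees("abcde"))
        assert len({t for t in trees}) == len(trees)

    def test_capacity_guard(self):
        with pytest.raises(CapacityError):
            list(enumerate_rooted_binary_trees("abcdefghij"))

    def test_all_trees_binary(self):
        assert all(t.is_binary for t in enumerate_rooted_binary_trees("abcde"))


class TestCounting:
    def test_counterexample_displayed_by_no_tree(self):
        assert count_displaying_trees(fx.FIG1_COUNTEREXAMPLE_R, "abcdef") == 0

    def test_single_triple(self):
        assert count_displaying_trees([RootedTriple("a", "b", "c")], "abc") == 1

    def test_two_disjoint_triples_closed_form(self):
        R = [RootedTriple("a", "b", "c"), RootedTriple("d", "e", "f")]
        assert count_displaying_trees(R, "abcdef") == 105 == disjoint_display_count(6)

    @pytest.mark.parametrize(
        "n,expected", [(3, 1), (6, 105), (9, 75075)]
    )
    def test_disjoint_closed_form_values(self, n, expected):
        assert disjoint_display_count(n) == expected

    def test_disjoint_rejects_bad_n(self):
        for n in (0, 2, 4, -3):
            with pytest.raises(SetSystemError):
                disjoint_display_count(n)

    def test_count_matches_naive_filter(self):
        rng = random.Random(31)
        for _ in range(5):
            R = [RootedTriple(*rng.sample("abcde", 3)) for _ in range(2)]
            naive = sum(
                1
                for t in enumerate_rooted_binary_trees("abcde")
                if all(displays_triple(t, r) for r in R)
            )
            assert count_displaying_trees(R, "abcde") == naive


class TestUniqueDefiningTriples:
    def test_three_leaves(self):
        assert unique_defining_triples(T((("a", "b"), "c"))) == TripleSet(["a,b|c"])

    def test_four_leaf_caterpillar(self):
        tree = T(((("a", "b"), "c"), "d"))
        R = unique_defining_triples(tree)
        assert len(R) == 2 and RootedTriple("a", "b", "c") in R
        displaying = [
            t
            for t in enumerate_rooted_binary_trees("abcd")
            if all(displays_triple(t, r) for r in R)
        ]
        assert displaying == [tree]

    def test_six_leaf_trees_unique_and_thin(self):
        from phyloflex import SetSystem, is_thin

        for seed in range(8):
            tree = fx.random_rooted_binary_tree("abcdef", seed)
            R = unique_defining_triples(tree)
            assert len(R) == 4
            assert count_displaying_trees(R, "abcdef") == 1
            assert all(displays_triple(tree, t) for t in R)
            assert is_thin(SetSystem(R.support))[0]

    def test_rejects_non_binary(self):
        with pytest.raises(SetSystemError):
            unique_defining_triples(RootedTree.from_nested(("a", "b", "c")))


class TestTreeBasics:
    def test_newick_canonical(self):
        tree = T((("d", "c"), ("b", "a")))
        assert tree.to_newick() == "((a,b),(c,d));"

    def test_equality_by_clusters(self):
        assert T((("a", "b"), "c")) == T((("b", "a"), "c"))
        assert T((("a", "b"), "c")) != T((("a", "c"), "b"))

    def test_prune_leaf_suppresses_degree2(self):
        tree = T(((("a", "b"), "c"), "d"))
        assert tree.prune_leaf("a") == T((("b", "c"), "d"))

    def test_duplicate_leaf_rejected(self):
        with pytest.raises(SetSystemError):
            T((("a", "a"), "c"))
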