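"""Set-system model, excess functions, thin/slim deciders, SDR, patchwork."""

import itertools

import pytest

from phyloflex import (
    BlockSizeError,
    CapacityError,
    SetSystem,
    SetSystemError,
    UniformityError,
    excess_general,
    excess_uniform,
    has_sdr_after_deletion,
    is_slim,
    is_thin,
    leaf_union,
    make_block,
    occurrence_counts,
    zero_excess_family_is_patchwork,
)
from phyloflex import fixtures as fx

from conftest import random_mixed_systems, random_small_systems, random_thin_batch


def B(*labels):
    return frozenset(labels)


class TestModel:
    def test_leaf_union(self):
        assert leaf_union(fx.FIG1_TAU.blocks) == frozenset("abcdef")
        assert leaf_union([]) == frozenset()
        assert leaf_union([B("a", "b", "c")]) == B("a", "b", "c")

    def test_labels_validated(self):
        with pytest.raises(SetSystemError):
            make_block(["a,b", "c", "d"])
        with pytest.raises(SetSystemError):
            make_block(["a|x", "c", "d"])
        with pytest.raises(BlockSizeError):
            make_block(["a"])

    def test_duplicate_blocks_rejected_or_deduped(self):
        with pytest.raises(SetSystemError, match="duplicate"):
            SetSystem([["a", "b", "c"], ["c", "b", "a"]])
        with pytest.warns(UserWarning, match="duplicate"):
            sys_ = SetSystem([["a", "b", "c"], ["c", "b", "a"]], dedupe=True)
        assert len(sys_) == 1

    def test_universe_must_cover_blocks(self):
        with pytest.raises(SetSystemError, match="outside universe"):
            SetSystem([["a", "b", "c"]], universe=["a", "b"])
        sys_ = SetSystem([["a", "b", "c"]], universe="abcd")
        assert sys_.universe == frozenset("abcd")
        assert sys_.leaves == frozenset("abc")


class TestExcess:
    def test_uniform_values(self):
        # the five-block extension has excess -1; the four-block core 0
        assert excess_uniform(fx.FIG1_TAU_PRIME.blocks, 3) == -1
        assert excess_uniform(fx.FIG1_TAU.blocks, 3) == 0
        assert excess_uniform([B("a", "b", "c")], 3) == 0

    def test_uniformity_enforced(self):
        with pytest.raises(UniformityError):
            excess_uniform([B("a", "b", "c"), B("a", "b", "c", "d")], 3)
        with pytest.raises(SetSystemError):
            excess_uniform([], 3)

    def test_general_values(self):
        assert excess_general([B("a", "b", "c", "d")]) == 0
        assert excess_general([B("a", "b", "c", "d"), B("b", "c", "d", "e")]) == -1
        assert excess_general(fx.FIG1_TAU_PRIME.blocks) == -1

    def test_general_rejects_pairs(self):
        with pytest.raises(BlockSizeError):
            excess_general([B("a", "b")])

    def test_general_agrees_with_uniform_on_size3(self):
        for sys_ in random_small_systems(25, seed=3):
            for k in range(1, len(sys_) + 1):
                for sub in itertools.combinations(sys_.blocks, k):
                    assert excess_general(sub) == excess_uniform(sub, 3)


class TestThinSlim:
    def test_fig1_verdicts(self):
        ok, rep = is_thin(fx.FIG1_TAU, method="brute")
        assert ok and rep.excess == 0
        ok, rep = is_thin(fx.FIG1_TAU_PRIME, method="brute")
        assert not ok and rep.excess == -1
        # the full five-block collection itself attains the minimum
        assert excess_uniform(fx.FIG1_TAU_PRIME.blocks, 3) == rep.excess

    def test_sec1_tau_thin(self):
        ok, _ = is_thin(SetSystem([B("a", "b", "c"), B("c", "d", "e"),
                                   B("b", "e", "f"), B("a", "d", "f")]))
        assert ok

    def test_witness_recomputes(self):
        _, rep = is_thin(fx.FIG1_TAU_PRIME, method="brute")
        assert excess_uniform(rep.subset, 3) == rep.excess
        assert set(rep.subset) <= set(fx.FIG1_TAU_PRIME.blocks)

    def test_slim_examples(self):
        ok, _ = is_slim(fx.FIG1_TAU)
        assert ok  # thin = slim at block size 3
        ok, rep = is_slim(SetSystem([B("a", "b", "c", "d"), B("b", "c", "d", "e")]))
        assert not ok and rep.excess == -1
        ok, _ = is_slim(SetSystem([B("a", "b", "c", "d", "e")]))
        assert ok

    def test_slim_rejects_pairs(self):
        with pytest.raises(BlockSizeError):
            is_slim(SetSystem([B("a", "b")]))

    def test_thin_rejects_mixed(self):
        with pytest.raises(UniformityError):
            is_thin(SetSystem([B("a", "b", "c"), B("a", "b", "c", "d")]))

    def test_brute_ceiling(self):
        sys_ = fx.random_thin_system(6, 3, seed=0)
        with pytest.raises(CapacityError):
            is_thin(sys_, method="brute", max_bruteforce=5)

    def test_slim_equals_thin_at_r3_and_implies_thin_at_r4(self):
        for sys_ in random_small_systems(30, seed=11):
            assert is_slim(sys_, "brute")[0] == is_thin(sys_, "brute")[0]
        for sys_ in random_small_systems(30, block_size=4, max_taxa=8, seed=12):
            slim = is_slim(sys_, "brute")[0]
            if slim:
                assert is_thin(sys_, "brute")[0]

    def test_heredity_of_thin(self):
        for sys_ in random_thin_batch(20, seed=5):
            for k in range(1, len(sys_) + 1):
                for sub in itertools.combinations(sys_.blocks, k):
                    assert excess_uniform(sub, 3) >= 0

    def test_size_bound_for_thin_covering_systems(self):
        # thin with L(tau) = X implies |tau| <= |X| - r + 1
        for sys_ in random_thin_batch(30, seed=6):
            n, r = len(sys_.leaves), 3
            assert len(sys_) <= n - r + 1
        for nb in (1, 2, 4, 6):
            sys_ = fx.random_thin_system(nb, 2, seed=nb)
            assert len(sys_) <= len(sys_.leaves) - 1


class TestOccurrence:
    def test_fig1_counts(self):
        counts = occurrence_counts(fx.FIG1_TAU)
        assert counts == {"a": 2, "b": 3, "c": 2, "d": 2, "e": 2, "f": 1}

    def test_sum_identity_and_low_occurrence(self):
        for sys_ in random_thin_batch(20, seed=7):
            counts = occurrence_counts(sys_)
            assert sum(counts.values()) == sum(len(b) for b in sys_.blocks)
            # a thin covering system always has a taxon in <= r-1 blocks
            assert min(counts.values()) <= 2

    def test_single_block(self):
        assert occurrence_counts(SetSystem([B("a", "b", "c")])) == {
            "a": 1, "b": 1, "c": 1,
        }

    def test_fig1_prime_minimum(self):
        counts = occurrence_counts(fx.FIG1_TAU_PRIME)
        assert counts["f"] == 1 == min(counts.values())


class TestSDR:
    def test_thin_system_always_has_sdr(self):
        ok, rep = has_sdr_after_deletion(fx.FIG1_TAU, {"a", "b"})
        assert ok
        # representatives are distinct and chosen from the residual sets
        assert len(set(rep.values())) == len(fx.FIG1_TAU)
        for block, taxon in rep.items():
            assert taxon in block - {"a", "b"}

    def test_non_thin_counterexample(self):
        # residuals {b},{b,d},{b,e},{d,e,f},{b,d,e} under B={a,c}:
        # the four sets {b},{b,d},{b,e},{b,d,e} only cover {b,d,e}
        ok, rep = has_sdr_after_deletion(fx.FIG1_TAU_PRIME, {"a", "c"})
        assert not ok and rep is None

    def test_sdr_for_every_deletion_set_of_thin_systems(self):
        for sys_ in random_thin_batch(10, seed=9):
            for Bset in itertools.combinations(sorted(sys_.leaves), 2):
                assert has_sdr_after_deletion(sys_, Bset)[0]

    def test_bad_deletion_size(self):
        with pytest.raises(SetSystemError):
            has_sdr_after_deletion(fx.FIG1_TAU, {"a"})

    def test_singleton(self):
        ok, rep = has_sdr_after_deletion(SetSystem([B("a", "b", "c")]), {"a", "b"})
        assert ok and rep == {B("a", "b", "c"): "c"}


class TestPatchwork:
    def test_fixture_systems(self):
        assert zero_excess_family_is_patchwork(fx.FIG3_TAU)
        assert zero_excess_family_is_patchwork(fx.SEC1_TAU)
        assert zero_excess_family_is_patchwork(SetSystem([B("a", "b", "c")]))

    def test_rejects_non_slim(self):
        with pytest.raises(SetSystemError, match="slim"):
            zero_excess_family_is_patchwork(fx.FIG1_TAU_PRIME)

    def test_random_slim_systems(self):
        checked = 0
        for sys_ in random_thin_batch(30, seed=13):
            assert zero_excess_family_is_patchwork(sys_)
            checked += 1
        for sys_ in random_mixed_systems(40, seed=14):
            if is_slim(sys_, "brute")[0]:
                assert zero_excess_family_is_patchwork(sys_)
                checked += 1
        assert checked >= 50
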