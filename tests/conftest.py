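"""Shared generators for seeded random test instances."""

from __future__ import annotations

import random

import pytest

from phyloflex import SetSystem
from phyloflex import fixtures as fx


def random_small_systems(n, *, max_taxa=7, max_blocks=5, block_size=3, seed=0):
    """n seeded random uniform systems within the given caps."""
    rng = random.Random(seed)
    out = []
    attempt = 0
    while len(out) < n:
        attempt += 1
        n_taxa = rng.randint(block_size + 1, max_taxa)
        import math

        n_blocks = rng.randint(1, min(max_blocks, math.comb(n_taxa, block_size)))
        out.append(fx.random_set_system(n_taxa, n_blocks, block_size, seed * 10_000 + attempt))
    return out


def random_mixed_systems(n, *, sizes=(3, 4), max_blocks=3, max_taxa=7, seed=0):
    """n seeded random systems with mixed block sizes (distinct blocks)."""
    rng = random.Random(seed)
    out = []
    while len(out) < n:
        n_taxa = rng.randint(max(sizes) + 1, max_taxa)
        taxa = [chr(ord("a") + i) for i in range(n_taxa)]
        n_blocks = rng.randint(1, max_blocks)
        blocks: set = set()
        guard = 0
        while len(blocks) < n_blocks and guard < 100:
            guard += 1
            blocks.add(frozenset(rng.sample(taxa, rng.choice(sizes))))
        out.append(SetSystem(blocks))
    return out


def random_thin_batch(n, *, block_size=3, max_taxa=10, blocks_range=(2, 5), seed=0):
    """n guaranteed-thin systems with leaf sets capped at max_taxa."""
    rng = random.Random(seed)
    out = []
    attempt = 0
    while len(out) < n:
        attempt += 1
        nb = rng.randint(*blocks_range)
        sys_ = fx.random_thin_system(nb, block_size, seed * 10_000 + attempt)
        if len(sys_.leaves) <= max_taxa:
            out.append(sys_)
    return out


@pytest.fixture(scope="session")
def thin_systems_100():
    return random_thin_batch(100, seed=8)
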