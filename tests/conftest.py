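"""Shared fixtures and brute-force per-base oracles.

The oracles deliberately ignore every optimization in the package: they
paint intervals onto boolean arrays and count bases, or compare every
interval pair, so any agreement with the fast implementations is evidence,
not tautology.
"""

from __future__ import annotations

import numpy as np
import pytest

from reachmap.interval_core import GenomeDef, IntervalSet


@pytest.fixture
def toy_genome() -> GenomeDef:
    return GenomeDef([("chrA", 100_000), ("chrB", 60_000)])


def random_interval_set(
    rng: np.random.Generator,
    genome: GenomeDef,
    n: int,
    max_len: int = 500,
) -> IntervalSet:
    chroms, starts, ends = [], [], []
    names = list(genome.names)
    for _ in range(n):
        c = names[rng.integers(0, len(names))]
        L = genome.length(c)
        length = int(rng.integers(1, max_len + 1))
        s = int(rng.integers(0, L - length + 1))
        chroms.append(c)
        starts.append(s)
        ends.append(s + length)
    return IntervalSet(chroms, starts, ends, genome=genome)


def coverage_mask(iset: IntervalSet, genome: GenomeDef) -> dict[str, np.ndarray]:
    """Per-base boolean coverage arrays — the brute-force footprint."""
    masks = {c: np.zeros(L, dtype=bool) for c, L in genome.chromosomes}
    for iv in iset:
        masks[iv.chrom][iv.start : iv.end] = True
    return masks


def oracle_overlap(A: IntervalSet, B: IntervalSet, genome: GenomeDef) -> dict:
    """All overlap statistics by per-base masks and all-pairs comparison."""
    mB = coverage_mask(B, genome)
    mA = coverage_mask(A, genome)
    n_A_hit = sum(1 for iv in A if mB[iv.chrom][iv.start : iv.end].any())
    n_B_hit = sum(1 for iv in B if mA[iv.chrom][iv.start : iv.end].any())
    inter = sum(int((mA[c] & mB[c]).sum()) for c in mA)
    union = sum(int((mA[c] | mB[c]).sum()) for c in mA)
    return {
        "n_A_hit": n_A_hit,
        "n_B_hit": n_B_hit,
        "bp_intersect": inter,
        "jaccard": inter / union if union else 0.0,
    }


def oracle_covered_bp(iset: IntervalSet, genome: GenomeDef) -> int:
    return sum(int(m.sum()) for m in coverage_mask(iset, genome).values())
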