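"""Shared fixtures: small genomes, random interval sets, brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from enhconcord import GenomeSpec, Interval, IntervalSet, intervals_overlap


@pytest.fixture
def genome() -> GenomeSpec:
    return GenomeSpec({"chr1": 1_000_000, "chr2": 1_000_000})


@pytest.fixture
def tiny_genome() -> GenomeSpec:
    return GenomeSpec({"chrA": 1000, "chrB": 500})


def random_interval_set(
    rng: np.random.Generator,
    genome: GenomeSpec,
    n: int,
    label: str,
    min_len: int = 50,
    max_len: int = 800,
) -> IntervalSet:
    chroms = genome.chroms
    clens = [genome.chrom_lengths[c] for c in chroms]
    ivs = []
    for i in range(n):
        ci = int(rng.integers(0, len(chroms)))
        length = int(rng.integers(min_len, min(max_len, clens[ci]) + 1))
        start = int(rng.integers(0, clens[ci] - length + 1))
        ivs.append(Interval(chroms[ci], start, start + length, f"{label}_{i}"))
    return IntervalSet(label=label, intervals=ivs)


def brute_force_overlap_count(query: IntervalSet, reference: IntervalSet):
    """All-pairs O(n*m) oracle for `-wa -u` counting: names of query
    intervals hitting >= 1 reference interval."""
    found = []
    for q in query:
        if any(intervals_overlap(q, r) for r in reference):
            found.append(q.name)
    return found
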