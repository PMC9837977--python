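"""Overlap counting and shuffle-permutation significance.

The overlap contract follows ``bedtools intersect -wa -u``: a query
interval is counted at most once, and counted iff it shares at least one
basepair with any reference interval. Significance of an observed overlap
count is assessed against a null built by relocating every query interval
uniformly at random on the genome (``bedtools shuffle`` style), recounting
``n_perm`` times, and converting the observed count to a z-score against
the permuted mean and sample standard deviation. Two-tailed p-values use
the normal approximation to the permuted distribution; with n_perm = 500
the empirical tail is far too coarse for Bonferroni-level thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .intervals import GenomeSpec, Interval, IntervalSet

__all__ = [
    "OverlapResult",
    "PermutationResult",
    "ReferenceIndex",
    "count_overlapping",
    "found_mask",
    "percent",
    "shuffle_set",
    "permutation_test",
    "bonferroni_alpha",
    "classify",
    "select_best_matching",
]

ENRICHED = "enriched"
DEPLETED = "depleted"
NOT_SIGNIFICANT = "not_significant"
DEGENERATE = "degenerate"


@dataclass
class OverlapResult:
    """Result of counting query intervals that hit >= 1 reference interval."""

    query_label: str
    reference_label: str
    n_query: int
    n_overlapping: int
    found_names: List[str] = field(default_factory=list)

    @property
    def fraction_pct(self) -> float:
        """100 x n_overlapping / n_query (unrounded percent)."""
        if self.n_query == 0:
            raise ValueError("fraction undefined for empty query set")
        return 100.0 * self.n_overlapping / self.n_query


@dataclass
class PermutationResult:
    """Observed overlap vs the shuffle null: z-score, p, and classification.

    ``classification`` is ``degenerate`` iff the permuted counts had zero
    standard deviation, in which case ``z`` and ``p_two_tailed`` are None
    rather than silently infinite.
    """

    observed: int
    n_perm: int
    perm_mean: float
    perm_sd: float
    z: Optional[float]
    p_two_tailed: Optional[float]
    alpha_adjusted: float
    classification: str
    perm_counts: Optional[np.ndarray] = None


class ReferenceIndex:
    """Per-chromosome merged reference spans supporting O(log n) hit tests.

    Merging makes spans disjoint and sorted, so a query [s, e) overlaps the
    reference iff the last merged span starting before e ends after s.
    """

    def __init__(self, reference: IntervalSet):
        self.label = reference.label
        self._spans: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in reference.by_chrom().items():
            starts: List[int] = []
            ends: List[int] = []
            for s, e in _merge(sorted((iv.start, iv.end) for iv in ivs)):
                starts.append(s)
                ends.append(e)
            self._spans[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )

    def hits(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Boolean mask: which [start, end) queries on chrom hit the reference."""
        spans = self._spans.get(chrom)
        if spans is None or len(spans[0]) == 0:
            return np.zeros(len(starts), dtype=bool)
        ref_starts, ref_ends = spans
        idx = np.searchsorted(ref_starts, ends, side="left") - 1
        ok = idx >= 0
        hit = np.zeros(len(starts), dtype=bool)
        hit[ok] = ref_ends[idx[ok]] > starts[ok]
        return hit

    @property
    def covered_bases(self) -> int:
        return int(sum((e - s).sum() for s, e in self._spans.values()))


def _merge(spans: Sequence[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def found_mask(query: IntervalSet, reference: IntervalSet | ReferenceIndex) -> np.ndarray:
    """Per-query boolean vector (in the query's deterministic order):
    True iff the query interval overlaps >= 1 reference interval."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    mask = np.zeros(len(query), dtype=bool)
    chroms = np.array([iv.chrom for iv in query])
    starts = np.array([iv.start for iv in query], dtype=np.int64)
    ends = np.array([iv.end for iv in query], dtype=np.int64)
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        mask[sel] = index.hits(str(chrom), starts[sel], ends[sel])
    return mask


def count_overlapping(query: IntervalSet, reference: IntervalSet | ReferenceIndex) -> OverlapResult:
    """Count query intervals overlapping the reference (``-wa -u`` semantics)."""
    if len(query) == 0:
        raise ValueError("empty query set: overlap fraction undefined")
    mask = found_mask(query, reference)
    names = [iv.name for iv, hit in zip(query, mask) if hit]
    label = reference.label if isinstance(reference, ReferenceIndex) else reference.label
    return OverlapResult(
        query_label=query.label,
        reference_label=label,
        n_query=len(query),
        n_overlapping=int(mask.sum()),
        found_names=names,
    )


def percent(numerator: int, denominator: int) -> int:
    """Integer percent, rounded half away from zero (e.g. 8779/11549 -> 76)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


# ---------------------------------------------------------------------------
# shuffle null


def _placement_geometry(genome: GenomeSpec) -> Tuple[List[str], np.ndarray]:
    chroms = genome.chroms
    clens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=np.int64)
    return chroms, clens


def _draw_placements(
    lengths: np.ndarray, clens: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Uniform draw over every valid (chrom, start) genome-wide, per interval.

    A length-L interval has ``clen - L + 1`` valid starts on a chromosome of
    length clen; one placement is drawn uniformly from the union across
    chromosomes, so long chromosomes receive proportionally more intervals.
    """
    valid = np.maximum(clens[:, None] - lengths[None, :] + 1, 0)  # (n_chrom, n)
    totals = valid.sum(axis=0)
    if np.any(totals == 0):
        bad = int(lengths[totals == 0][0])
        raise ValueError(f"interval of length {bad} does not fit on any chromosome")
    u = rng.integers(0, totals)
    cum = np.cumsum(valid, axis=0)
    chrom_idx = (u[None, :] < cum).argmax(axis=0)
    n = len(lengths)
    prev = np.where(chrom_idx > 0, cum[chrom_idx - 1, np.arange(n)], 0)
    starts = u - prev
    return chrom_idx, starts


def derive_seed(master_seed: int, index: int) -> int:
    """Deterministic, order-independent per-permutation seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def shuffle_set(interval_set: IntervalSet, genome: GenomeSpec, rng_seed: int) -> IntervalSet:
    """Relocate every interval independently and uniformly on the genome.

    Lengths, names and count are preserved; shuffled intervals may overlap
    one another (no mutual-exclusion constraint, as in the shuffle tool's
    default). Deterministic given the seed.
    """
    chroms, clens = _placement_geometry(genome)
    lengths = np.array([iv.length for iv in interval_set], dtype=np.int64)
    rng = np.random.default_rng(rng_seed)
    chrom_idx, starts = _draw_placements(lengths, clens, rng)
    shuffled = [
        Interval(chroms[ci], int(s), int(s) + int(l), iv.name)
        for iv, ci, s, l in zip(interval_set, chrom_idx, starts, lengths)
    ]
    return IntervalSet(label=interval_set.label, intervals=shuffled,
                       metadata=dict(interval_set.metadata))


def _count_placements(
    chrom_idx: np.ndarray,
    starts: np.ndarray,
    lengths: np.ndarray,
    chroms: List[str],
    index: ReferenceIndex,
) -> int:
    hits = 0
    for ci in np.unique(chrom_idx):
        sel = chrom_idx == ci
        s = starts[sel]
        hits += int(index.hits(chroms[int(ci)], s, s + lengths[sel]).sum())
    return hits


def permutation_test(
    query: IntervalSet,
    reference: IntervalSet | ReferenceIndex,
    genome: GenomeSpec,
    n_perm: int = 500,
    rng_seed: int = 0,
    alpha_adjusted: float = 0.01,
    keep_counts: bool = False,
) -> PermutationResult:
    """Shuffle-permutation z-test of the observed overlap count.

    The query is relocated uniformly on the genome ``n_perm`` times
    (permutation i uses a seed derived deterministically from
    ``(rng_seed, i)``, so results are reproducible and order-independent);
    the observed count is converted to a z-score against the permuted
    sample mean and sample (n-1) standard deviation, with a two-tailed
    normal p-value. Classification at ``alpha_adjusted`` distinguishes
    enrichment (z > 0) from depletion (z < 0).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if len(query) == 0:
        raise ValueError("empty query set")
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    observed = count_overlapping(query, index).n_overlapping

    chroms, clens = _placement_geometry(genome)
    lengths = np.array([iv.length for iv in query], dtype=np.int64)
    counts = np.empty(n_perm, dtype=np.int64)
    for i in range(1, n_perm + 1):
        rng = np.random.default_rng(derive_seed(rng_seed, i))
        chrom_idx, starts = _draw_placements(lengths, clens, rng)
        counts[i - 1] = _count_placements(chrom_idx, starts, lengths, chroms, index)

    perm_mean = float(counts.mean())
    perm_sd = float(counts.std(ddof=1))
    if perm_sd == 0.0:
        return PermutationResult(
            observed=observed, n_perm=n_perm, perm_mean=perm_mean, perm_sd=0.0,
            z=None, p_two_tailed=None, alpha_adjusted=alpha_adjusted,
            classification=DEGENERATE,
            perm_counts=counts if keep_counts else None,
        )
    z = (observed - perm_mean) / perm_sd
    p = float(2.0 * stats.norm.sf(abs(z)))
    result = PermutationResult(
        observed=observed, n_perm=n_perm, perm_mean=perm_mean, perm_sd=perm_sd,
        z=float(z), p_two_tailed=p, alpha_adjusted=alpha_adjusted,
        classification="", perm_counts=counts if keep_counts else None,
    )
    result.classification = classify(result, alpha_adjusted)
    return result


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m comparisons."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha {alpha} not in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def classify(result: PermutationResult, alpha_adjusted: float) -> str:
    """enriched / depleted / not_significant at the adjusted threshold."""
    if result.perm_sd == 0.0 or result.z is None or result.p_two_tailed is None:
        return DEGENERATE
    if result.p_two_tailed < alpha_adjusted:
        return ENRICHED if result.z > 0 else DEPLETED
    return NOT_SIGNIFICANT


def select_best_matching(candidates: Mapping[str, OverlapResult]) -> str:
    """Label of the candidate with the highest overlap fraction.

    Ties break lexicographically by label so selection is deterministic.
    """
    if not candidates:
        raise ValueError("no candidates")
    return min(candidates, key=lambda lab: (-candidates[lab].fraction_pct, lab))
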