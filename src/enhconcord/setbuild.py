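"""Construction of analysis-ready enhancer sets.

Mirrors the curation steps applied to reporter-assay enhancer downloads
before any comparison: a maximum-length filter (long entries may span
several independent regulatory elements), greedy smallest-feature
de-overlapping, tissue grouping from expression-pattern annotations, and
a >= support-fraction consensus merge across replicate tracks (the rule
used when chromatin tracks are integrated into a consensus profile).
"""

from __future__ import annotations

import math
import warnings
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .intervals import Interval, IntervalSet

__all__ = [
    "TissueAnnotation",
    "TrackBundle",
    "filter_by_length",
    "select_smallest_nonoverlapping",
    "group_by_tissue",
    "consensus_merge",
    "read_annotations",
    "read_tissue_map",
]


@dataclass(frozen=True)
class TissueAnnotation:
    """Expression-pattern annotation: one interval, one or more tissue terms."""

    interval_name: str
    tissues: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tissues:
            raise ValueError(f"annotation for {self.interval_name!r} has no tissue terms")


@dataclass
class TrackBundle:
    """Replicate tracks to be merged into a consensus set.

    ``support_fraction`` is the minimum fraction of tracks that must cover a
    base for it to enter the consensus (default 0.5, i.e. "at least half").
    """

    tracks: List[IntervalSet]
    support_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("bundle must contain at least one track")
        if not (0.0 < self.support_fraction <= 1.0):
            raise ValueError(f"support_fraction {self.support_fraction} not in (0, 1]")


def filter_by_length(interval_set: IntervalSet, max_len: int) -> IntervalSet:
    """Retain intervals of length <= max_len (inclusive cutoff), order preserved."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = [iv for iv in interval_set if iv.length <= max_len]
    return IntervalSet(label=interval_set.label, intervals=kept,
                       metadata=dict(interval_set.metadata))


def select_smallest_nonoverlapping(interval_set: IntervalSet) -> IntervalSet:
    """Greedy smallest-feature de-overlap.

    Intervals are considered in order of (length asc, chrom, start, name);
    each is accepted iff it overlaps no already-accepted interval. Shorter
    features therefore displace every longer feature they touch, and the
    output is pairwise non-overlapping. Idempotent.
    """
    order = sorted(interval_set, key=lambda iv: (iv.length, iv.chrom, iv.start, iv.name))
    # accepted intervals per chromosome, kept sorted by start; since they are
    # pairwise disjoint only the two neighbours of a candidate can overlap it
    accepted: Dict[str, List[Tuple[int, int]]] = {}
    out: List[Interval] = []
    for iv in order:
        spans = accepted.setdefault(iv.chrom, [])
        i = bisect_left(spans, (iv.start, iv.end))
        clash = (i > 0 and spans[i - 1][1] > iv.start) or (
            i < len(spans) and spans[i][0] < iv.end
        )
        if not clash:
            insort(spans, (iv.start, iv.end))
            out.append(iv)
    return IntervalSet(label=interval_set.label, intervals=out,
                       metadata=dict(interval_set.metadata))


def group_by_tissue(
    interval_set: IntervalSet,
    annotations: Iterable[TissueAnnotation],
    tissue_map: Mapping[str, str],
) -> Dict[str, IntervalSet]:
    """Place intervals into tissue groups via their annotation terms.

    An interval joins every group that any of its terms maps to
    (multi-membership allowed). Terms absent from ``tissue_map`` are
    ignored; annotation names absent from the set trigger a warning and are
    skipped. Empty groups are omitted from the result.
    """
    if not tissue_map:
        raise ValueError("tissue_map is empty")
    by_name = {iv.name: iv for iv in interval_set}
    groups: Dict[str, List[Interval]] = {}
    for ann in annotations:
        iv = by_name.get(ann.interval_name)
        if iv is None:
            warnings.warn(
                f"annotation for unknown interval {ann.interval_name!r} skipped",
                stacklevel=2,
            )
            continue
        for term in ann.tissues:
            group = tissue_map.get(term)
            if group is None:
                continue
            members = groups.setdefault(group, [])
            if iv not in members:
                members.append(iv)
    return {
        group: IntervalSet(label=group, intervals=members)
        for group, members in sorted(groups.items())
        if members
    }


def _merged_spans(intervals: Sequence[Interval]) -> List[Tuple[int, int]]:
    """Union of possibly-overlapping spans on one chromosome."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    out: List[Tuple[int, int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def consensus_merge(bundle: TrackBundle) -> IntervalSet:
    """Consensus of replicate tracks: bases covered by enough tracks.

    Per-base support counts each track at most once (a track's internally
    overlapping intervals are unioned first). The consensus is the set of
    maximal runs with support >= ceil(support_fraction x n_tracks); with
    "at least 50%" of 3 tracks the threshold is 2. Output intervals are
    named ``consensus_<k>`` in (chrom, start) order. With a single track
    this reduces to the track's merged union.
    """
    n_tracks = len(bundle.tracks)
    threshold = math.ceil(bundle.support_fraction * n_tracks)
    # breakpoint sweep: +1 at each merged-span start, -1 at each end
    events: Dict[str, List[Tuple[int, int]]] = {}
    for track in bundle.tracks:
        for chrom, ivs in track.by_chrom().items():
            ev = events.setdefault(chrom, [])
            for s, e in _merged_spans(ivs):
                ev.append((s, +1))
                ev.append((e, -1))
    out: List[Interval] = []
    for chrom in sorted(events):
        ev = sorted(events[chrom])
        support = 0
        run_start = None
        i = 0
        while i < len(ev):
            pos = ev[i][0]
            while i < len(ev) and ev[i][0] == pos:
                support += ev[i][1]
                i += 1
            if support >= threshold and run_start is None:
                run_start = pos
            elif support < threshold and run_start is not None:
                out.append(Interval(chrom, run_start, pos, ""))
                run_start = None
    named = [
        Interval(iv.chrom, iv.start, iv.end, f"consensus_{k}")
        for k, iv in enumerate(sorted(out, key=Interval.sort_key), start=1)
    ]
    return IntervalSet(label="consensus", intervals=named,
                       metadata={"n_tracks": n_tracks,
                                 "support_fraction": bundle.support_fraction})


def read_annotations(path) -> List[TissueAnnotation]:
    """Read a TSV of ``interval_name<TAB>tissue_term`` rows (one row per term)."""
    terms: Dict[str, List[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            name, term = line.split("\t")[:2]
            terms.setdefault(name, []).append(term)
    return [TissueAnnotation(name, tuple(ts)) for name, ts in sorted(terms.items())]


def read_tissue_map(path) -> Dict[str, str]:
    """Read a TSV of ``tissue_term<TAB>group`` rows."""
    mapping: Dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            term, group = line.split("\t")[:2]
            mapping[term] = group
    return mapping
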