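"""Core genomic-interval data model and BED / chrom.sizes I/O.

Coordinates follow the BED convention throughout: 0-based, half-open
``[start, end)``, so an interval of length ``L`` covers positions
``start .. start + L - 1``. Strand is ignored everywhere; the analyses
built on top of this module only ever use position and name.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

__all__ = [
    "Interval",
    "IntervalSet",
    "GenomeSpec",
    "BedParseError",
    "read_bed",
    "write_bed",
    "read_genome",
    "write_genome",
    "intervals_overlap",
]


class BedParseError(ValueError):
    """Raised for malformed BED / chrom.sizes input, naming the offending line."""


@dataclass(frozen=True)
class Interval:
    """A named genomic segment in 0-based half-open coordinates.

    Zero-length and negative-coordinate intervals are rejected at
    construction, so every ``Interval`` in the system is valid by type.
    """

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.start, int) or not isinstance(self.end, int):
            raise TypeError("interval coordinates must be integers")
        if self.start < 0:
            raise ValueError(f"negative start {self.start} for interval {self.name!r}")
        if self.start >= self.end:
            raise ValueError(
                f"zero- or negative-length interval {self.name!r}: "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> Tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.name)


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """True iff the two intervals share at least one basepair.

    Half-open semantics: ``[10, 20)`` and ``[20, 30)`` are adjacent, not
    overlapping. A single shared base (e.g. ``[10, 20)`` vs ``[19, 30)``)
    counts as overlap, matching ``bedtools intersect`` behaviour.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def _dedupe_names(intervals: Iterable[Interval]) -> List[Interval]:
    # Public BED files frequently repeat names; disambiguate with a numeric
    # suffix rather than erroring so the deterministic ordering stays total.
    seen: Dict[str, int] = {}
    out: List[Interval] = []
    for iv in intervals:
        name = iv.name
        if name in seen:
            seen[name] += 1
            new = f"{name}_{seen[name]}"
            while new in seen:
                seen[name] += 1
                new = f"{name}_{seen[name]}"
            seen[new] = 0
            iv = Interval(iv.chrom, iv.start, iv.end, new)
        else:
            seen[name] = 0
        out.append(iv)
    return out


@dataclass
class IntervalSet:
    """An ordered, named collection of intervals (a "dataset").

    Iteration order is deterministic: sorted by (chrom, start, end, name).
    Interval names are unique within a set; collisions are auto-suffixed.
    ``metadata`` carries free-form annotations such as assay type or the
    experiment-series (batch) identifier.
    """

    label: str
    intervals: List[Interval] = field(default_factory=list)
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = sorted(self.intervals, key=Interval.sort_key)
        self.intervals = _dedupe_names(ordered)
        # A rename can perturb the (…, name) tie-break; restore total order.
        self.intervals.sort(key=Interval.sort_key)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def names(self) -> List[str]:
        return [iv.name for iv in self.intervals]

    def by_chrom(self) -> Dict[str, List[Interval]]:
        out: Dict[str, List[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass
class GenomeSpec:
    """Chromosome-name -> length map; defines the space intervals shuffle over."""

    chrom_lengths: Dict[str, int]

    def __post_init__(self) -> None:
        if not self.chrom_lengths:
            raise ValueError("genome must contain at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if not isinstance(length, int) or length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())

    @property
    def chroms(self) -> List[str]:
        return sorted(self.chrom_lengths)

    def contains(self, iv: Interval) -> bool:
        return iv.chrom in self.chrom_lengths and iv.end <= self.chrom_lengths[iv.chrom]


_SKIP_PREFIXES = ("#", "browser", "track")


def read_bed(path: os.PathLike | str, label: Optional[str] = None) -> IntervalSet:
    """Read a BED file (>= 3 tab-separated columns) into an IntervalSet.

    browser/track/comment lines are skipped. A missing name column is filled
    with ``<label>_<line#>``. Columns beyond the 4th are preserved in
    ``metadata['extra_columns']`` keyed by interval name, but never used by
    any analysis stage.
    """
    if label is None:
        label = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    intervals: List[Interval] = []
    extra: Dict[str, Tuple[str, ...]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start = int(fields[1])
                end = int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from exc
            name = fields[3] if len(fields) >= 4 and fields[3] else f"{label}_{lineno}"
            try:
                iv = Interval(chrom, start, end, name)
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
            intervals.append(iv)
            if len(fields) > 4:
                extra[name] = tuple(fields[4:])
    metadata: Dict[str, object] = {}
    if extra:
        metadata["extra_columns"] = extra
    return IntervalSet(label=label, intervals=intervals, metadata=metadata)


def write_bed(interval_set: IntervalSet, path: os.PathLike | str) -> None:
    """Write a 4-column BED in the set's deterministic sort order.

    ``read_bed(write_bed(S))`` reproduces S's coordinates, names and count.
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in interval_set:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_genome(path: os.PathLike | str) -> GenomeSpec:
    """Read a UCSC chrom.sizes file (``<chrom>\\t<length>``)."""
    lengths: Dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected 2 columns")
            chrom = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer length {fields[1]!r}"
                ) from exc
            if chrom in lengths:
                raise BedParseError(f"{path}: line {lineno}: duplicate chromosome {chrom!r}")
            if length <= 0:
                raise BedParseError(f"{path}: line {lineno}: non-positive length {length}")
            lengths[chrom] = length
    return GenomeSpec(chrom_lengths=lengths)


def write_genome(genome: GenomeSpec, path: os.PathLike | str) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom in genome.chroms:
            fh.write(f"{chrom}\t{genome.chrom_lengths[chrom]}\n")
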