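"""Synthetic enhancer universe with recoverable ground truth.

Generates a small genome carrying non-overlapping "true" enhancers, a
reporter-assay-style query set (partial sensitivity, boundary jitter,
false positives placed off-truth), and several chromatin-assay-style
reference sets organised into experiment-series batches. Each batch has a
latent detectable subset of the truth: assays in a batch see only members
of that subset (each with probability ``assay_sensitivity``), so assays
from the same series recover correlated found-vectors while assays from
series with disjoint latent subsets do not — the batch-effect structure
the concordance stage is designed to expose.

Every quantity has a known generating parameter, so pipeline estimates
(overlap fractions, enrichment calls, within/between-batch correlation)
can be checked against closed-form expectations.
"""

from __future__ import annotations

import dataclasses
import json
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomeSpec, Interval, IntervalSet, write_bed, write_genome
from .setbuild import TissueAnnotation

__all__ = [
    "ReporterConfig",
    "BatchConfig",
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "SyntheticTissueWorld",
    "default_config",
    "make_world",
    "make_tissue_world",
    "expected_overlap_fraction",
    "place_avoiding",
    "export_world",
]

_MAX_ATTEMPTS_PER_INTERVAL = 1000


@dataclass
class ReporterConfig:
    """Reporter-style query set: sensitivity, false positives, edge jitter."""

    sensitivity: float = 0.7
    n_false_positives: int = 150
    boundary_jitter_bp: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0):
            raise ValueError("reporter sensitivity must be in [0, 1]")
        if self.n_false_positives < 0 or self.boundary_jitter_bp < 0:
            raise ValueError("counts and jitter must be non-negative")


@dataclass
class BatchConfig:
    """One experiment series: latent detectable subset + per-assay noise."""

    batch_label: str
    latent_fraction: float = 0.4
    n_assays: int = 5
    assay_sensitivity: float = 0.9
    assay_fp_count: int = 100

    def __post_init__(self) -> None:
        if not (0.0 < self.latent_fraction <= 1.0):
            raise ValueError("latent_fraction must be in (0, 1]")
        if not (0.0 <= self.assay_sensitivity <= 1.0):
            raise ValueError("assay_sensitivity must be in [0, 1]")
        if self.n_assays < 1 or self.assay_fp_count < 0:
            raise ValueError("n_assays >= 1 and assay_fp_count >= 0 required")


@dataclass
class SyntheticWorldConfig:
    """Full generating recipe; identical config + seed => identical world."""

    genome: GenomeSpec = field(
        default_factory=lambda: GenomeSpec({"chr1": 1_000_000, "chr2": 1_000_000})
    )
    n_true: int = 500
    length_range: Tuple[int, int] = (100, 1000)
    reporter: ReporterConfig = field(default_factory=ReporterConfig)
    batches: List[BatchConfig] = field(default_factory=lambda: [
        BatchConfig("seriesA"),
        BatchConfig("seriesB"),
    ])
    disjoint_batches: bool = True
    master_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.n_true < 1:
            raise ValueError("n_true must be >= 1")
        if self.n_true * hi > 0.5 * self.genome.total_length:
            raise ValueError(
                "placement infeasible: n_true x max length exceeds half the genome"
            )
        if self.disjoint_batches:
            total = sum(round(b.latent_fraction * self.n_true) for b in self.batches)
            if total > self.n_true:
                raise ValueError(
                    "disjoint latent subsets require sum(latent_fraction) <= 1"
                )

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["genome"] = dict(self.genome.chrom_lengths)
        d["length_range"] = list(self.length_range)
        return d


def default_config(master_seed: int = 0) -> SyntheticWorldConfig:
    """The standard two-series study world used throughout the analyses."""
    return SyntheticWorldConfig(master_seed=master_seed)


@dataclass
class SyntheticWorld:
    genome: GenomeSpec
    config: SyntheticWorldConfig
    true_enhancers: IntervalSet
    reporter_set: IntervalSet
    assay_sets: List[IntervalSet]
    truth_table: pd.DataFrame  # bool; rows: true enhancers, cols: set labels
    latent_subsets: Dict[str, List[str]]  # batch label -> true-enhancer names


@dataclass
class SyntheticTissueWorld:
    world: SyntheticWorld
    annotations: List[TissueAnnotation]
    tissue_map: Dict[str, str]
    groups: Dict[str, List[str]]  # group name -> true-enhancer names


class _DisjointPlacer:
    """Rejection-samples non-overlapping placements on the genome."""

    def __init__(self, genome: GenomeSpec):
        self.chroms = genome.chroms
        self.clens = np.array([genome.chrom_lengths[c] for c in self.chroms],
                              dtype=np.int64)
        self.spans: Dict[str, List[Tuple[int, int]]] = {c: [] for c in self.chroms}

    def _clashes(self, chrom: str, start: int, end: int) -> bool:
        spans = self.spans[chrom]
        i = bisect_left(spans, (start, end))
        return (i > 0 and spans[i - 1][1] > start) or (
            i < len(spans) and spans[i][0] < end
        )

    def draw(self, length: int, rng: np.random.Generator,
             register: bool = True) -> Tuple[str, int]:
        valid = np.maximum(self.clens - length + 1, 0)
        total = int(valid.sum())
        if total == 0:
            raise ValueError(f"interval of length {length} fits nowhere")
        cum = np.cumsum(valid)
        for _ in range(_MAX_ATTEMPTS_PER_INTERVAL):
            u = int(rng.integers(0, total))
            ci = int(np.searchsorted(cum, u, side="right"))
            start = u - (int(cum[ci - 1]) if ci > 0 else 0)
            chrom = self.chroms[ci]
            if not self._clashes(chrom, start, start + length):
                if register:
                    insort(self.spans[chrom], (start, start + length))
                return chrom, start
        raise ValueError(
            f"could not place interval of length {length} after "
            f"{_MAX_ATTEMPTS_PER_INTERVAL} attempts; genome too crowded"
        )


def place_avoiding(
    genome: GenomeSpec,
    avoid: IntervalSet,
    n: int,
    length_range: Tuple[int, int],
    rng: np.random.Generator,
    name_prefix: str = "fp",
) -> List[Interval]:
    """Place n random intervals that overlap nothing in ``avoid``.

    The placed intervals may overlap each other (they model independent
    spurious calls). Used both for false positives and for building
    deliberately depleted query sets.
    """
    placer = _DisjointPlacer(genome)
    for iv in avoid:
        insort(placer.spans[iv.chrom], (iv.start, iv.end))
    out: List[Interval] = []
    lo, hi = length_range
    for k in range(n):
        length = int(rng.integers(lo, hi + 1))
        chrom, start = placer.draw(length, rng, register=False)
        out.append(Interval(chrom, start, start + length, f"{name_prefix}_{k + 1}"))
    return out


def _jitter(iv: Interval, jitter_bp: int, clen: int,
            rng: np.random.Generator) -> Interval:
    if jitter_bp == 0:
        return iv
    ds = int(rng.integers(-jitter_bp, jitter_bp + 1))
    de = int(rng.integers(-jitter_bp, jitter_bp + 1))
    start = min(max(iv.start + ds, 0), clen - 1)
    end = min(max(iv.end + de, start + 1), clen)
    return Interval(iv.chrom, start, end, iv.name)


def make_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world from the config and master seed.

    Stages draw from independent streams spawned deterministically from the
    master seed, so e.g. adding a batch does not perturb the truth layout.
    """
    rng_truth, rng_reporter, rng_latent, rng_assay = (
        np.random.default_rng(np.random.SeedSequence(
            entropy=config.master_seed, spawn_key=(k,)))
        for k in range(4)
    )

    # 1. non-overlapping ground truth
    placer = _DisjointPlacer(config.genome)
    lo, hi = config.length_range
    true_ivs: List[Interval] = []
    for k in range(config.n_true):
        length = int(rng_truth.integers(lo, hi + 1))
        chrom, start = placer.draw(length, rng_truth)
        true_ivs.append(Interval(chrom, start, start + length, f"true_{k + 1}"))
    true_set = IntervalSet(label="true_enhancers", intervals=true_ivs)
    true_names = true_set.names  # deterministic order

    # 2. reporter-style query set
    rep = config.reporter
    include = rng_reporter.random(len(true_names)) < rep.sensitivity
    reporter_ivs: List[Interval] = []
    included_names: List[str] = []
    for iv, keep in zip(true_set, include):
        if keep:
            clen = config.genome.chrom_lengths[iv.chrom]
            reporter_ivs.append(_jitter(iv, rep.boundary_jitter_bp, clen, rng_reporter))
            included_names.append(iv.name)
    reporter_ivs.extend(place_avoiding(
        config.genome, true_set, rep.n_false_positives, config.length_range,
        rng_reporter, name_prefix="reporter_fp"))
    reporter_set = IntervalSet(label="reporter", intervals=reporter_ivs,
                               metadata={"assay": "reporter"})

    # 3. batches: latent detectable subsets, then per-assay detection + noise
    latent: Dict[str, List[str]] = {}
    if config.disjoint_batches:
        perm = rng_latent.permutation(len(true_names))
        offset = 0
        for b in config.batches:
            size = round(b.latent_fraction * config.n_true)
            idx = perm[offset:offset + size]
            offset += size
            latent[b.batch_label] = sorted(true_names[i] for i in idx)
    else:
        for b in config.batches:
            size = round(b.latent_fraction * config.n_true)
            idx = rng_latent.choice(len(true_names), size=size, replace=False)
            latent[b.batch_label] = sorted(true_names[i] for i in idx)

    by_name = {iv.name: iv for iv in true_set}
    assay_sets: List[IntervalSet] = []
    for b in config.batches:
        members = latent[b.batch_label]
        for a in range(1, b.n_assays + 1):
            label = f"{b.batch_label}_assay{a}"
            detect = rng_assay.random(len(members)) < b.assay_sensitivity
            ivs = [by_name[nm] for nm, d in zip(members, detect) if d]
            ivs = ivs + place_avoiding(
                config.genome, true_set, b.assay_fp_count, config.length_range,
                rng_assay, name_prefix=f"{label}_fp")
            assay_sets.append(IntervalSet(
                label=label, intervals=ivs,
                metadata={"batch": b.batch_label, "assay_index": a}))

    # 4. truth table: which sets contain each true enhancer (by name)
    columns = {"reporter": [nm in set(included_names) for nm in true_names]}
    for aset in assay_sets:
        present = {iv.name for iv in aset}
        columns[aset.label] = [nm in present for nm in true_names]
    truth = pd.DataFrame(columns, index=pd.Index(true_names, name="true_enhancer"))

    return SyntheticWorld(
        genome=config.genome, config=config, true_enhancers=true_set,
        reporter_set=reporter_set, assay_sets=assay_sets,
        truth_table=truth, latent_subsets=latent,
    )


def make_tissue_world(
    config: SyntheticWorldConfig,
    n_tissues: int,
    shared_fraction: float = 0.0,
) -> SyntheticTissueWorld:
    """World plus per-tissue true-enhancer groups and annotation records.

    True enhancers are partitioned round-robin into ``n_tissues`` groups; a
    ``shared_fraction`` of them additionally carries a second tissue term
    (multi-membership, as real expression annotations allow). The emitted
    TissueAnnotation records round-trip through tissue grouping to
    reproduce the generator's groups exactly.
    """
    if n_tissues < 1:
        raise ValueError("n_tissues must be >= 1")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must be in [0, 1]")
    world = make_world(config)
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.master_seed, spawn_key=(5,)))
    names = world.true_enhancers.names
    terms = [f"tissue_{(i % n_tissues) + 1}" for i in range(len(names))]
    annotations: List[TissueAnnotation] = []
    groups: Dict[str, List[str]] = {f"tissue_{t + 1}": [] for t in range(n_tissues)}
    for i, (nm, term) in enumerate(zip(names, terms)):
        tissue_terms = [term]
        if n_tissues > 1 and rng.random() < shared_fraction:
            other = f"tissue_{((i % n_tissues) + 1) % n_tissues + 1}"
            tissue_terms.append(other)
        annotations.append(TissueAnnotation(nm, tuple(sorted(set(tissue_terms)))))
        for t in tissue_terms:
            if nm not in groups[t]:
                groups[t].append(nm)
    tissue_map = {f"tissue_{t + 1}": f"tissue_{t + 1}" for t in range(n_tissues)}
    groups = {g: members for g, members in groups.items() if members}
    return SyntheticTissueWorld(world=world, annotations=annotations,
                                tissue_map=tissue_map, groups=groups)


def expected_overlap_fraction(
    config: SyntheticWorldConfig,
    batch_label: Optional[str] = None,
) -> float:
    """Closed-form expectation of the reporter-vs-single-assay overlap percent.

    A reporter true positive is found iff its enhancer is in the batch's
    latent subset (prob q) and the assay detects it (prob s_a). A reporter
    false positive can only collide with assay intervals by chance, with
    probability approximated by the assay's genomic footprint (each
    assay interval of mean length l catches a length-l query whose start
    lies within ~(l_assay + l_query) of it). Valid when jitter is small
    relative to the minimum enhancer length (jitter < min_length / 2).
    """
    batches = {b.batch_label: b for b in config.batches}
    b = batches[batch_label] if batch_label else config.batches[0]
    p_tp = b.latent_fraction * b.assay_sensitivity
    lo, hi = config.length_range
    mean_len = (lo + hi) / 2.0
    n_assay_iv = round(b.latent_fraction * config.n_true) * b.assay_sensitivity \
        + b.assay_fp_count
    p_fp = min(1.0, n_assay_iv * 2.0 * mean_len / config.genome.total_length)
    n_tp = config.reporter.sensitivity * config.n_true
    n_fp = config.reporter.n_false_positives
    if n_tp + n_fp == 0:
        raise ValueError("reporter set empty in expectation")
    return 100.0 * (n_tp * p_tp + n_fp * p_fp) / (n_tp + n_fp)


def export_world(world: SyntheticWorld, outdir,
                 annotations: Optional[Sequence[TissueAnnotation]] = None,
                 tissue_map: Optional[Dict[str, str]] = None) -> Dict[str, str]:
    """Write the world as BED files + chrom.sizes + truth table + config JSON.

    Returns a name -> path map of everything written. Byte-identical for
    identical worlds.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: Dict[str, str] = {}

    def _p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_genome(world.genome, _p("genome.chrom.sizes"))
    write_bed(world.true_enhancers, _p("true_enhancers.bed"))
    write_bed(world.reporter_set, _p("reporter.bed"))
    for aset in world.assay_sets:
        write_bed(aset, _p(f"{aset.label}.bed"))
    world.truth_table.astype(int).to_csv(_p("truth_table.tsv"), sep="\t")
    with open(_p("config.json"), "wt", encoding="utf-8") as fh:
        json.dump(world.config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(_p("batches.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("label\tbatch\n")
        for aset in world.assay_sets:
            fh.write(f"{aset.label}\t{aset.metadata['batch']}\n")
    if annotations is not None:
        with open(_p("annotations.tsv"), "wt", encoding="utf-8") as fh:
            for ann in annotations:
                for term in ann.tissues:
                    fh.write(f"{ann.interval_name}\t{term}\n")
    if tissue_map is not None:
        with open(_p("tissue_map.tsv"), "wt", encoding="utf-8") as fh:
            for term in sorted(tissue_map):
                fh.write(f"{term}\t{tissue_map[term]}\n")
    return paths
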