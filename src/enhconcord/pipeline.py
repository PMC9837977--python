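"""Orchestration of the three analyses over interval-set inputs.

``run_compare``   — pairwise query-vs-reference overlap with permutation
                    significance and enrichment/depletion classification.
``run_correlate`` — found-vector phi-correlation matrix across references,
                    with per-batch-pair summaries.
``run_simulate``  — generate and export a synthetic world bundle.

Each function takes an :class:`AnalysisConfig` (loadable from YAML/JSON)
and writes deterministic TSV/JSON reports: a fixed seed reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .concordance import correlation_matrix, export_matrix, found_vector, group_summary
from .intervals import GenomeSpec, IntervalSet, read_bed, read_genome
from .overlap import (
    ReferenceIndex,
    bonferroni_alpha,
    count_overlapping,
    percent,
    permutation_test,
)
from .setbuild import filter_by_length, select_smallest_nonoverlapping
from .synthetic import SyntheticWorldConfig, default_config, export_world, make_world

logger = logging.getLogger("enhconcord")

__all__ = ["AnalysisConfig", "run_compare", "run_correlate", "run_simulate"]

REPORT_COLUMNS = [
    "query_label", "reference_label", "n_query", "n_overlapping",
    "fraction_pct", "perm_mean", "perm_sd", "z", "p_two_tailed",
    "alpha_adjusted", "classification",
]


@dataclass
class AnalysisConfig:
    """Run parameters for the compare/correlate/simulate stages."""

    genome_path: Optional[str] = None
    query_paths: List[str] = field(default_factory=list)
    reference_paths: List[str] = field(default_factory=list)
    batch_labels: List[str] = field(default_factory=list)  # parallel to references
    length_cutoff: Optional[int] = None
    deoverlap: bool = True
    n_perm: int = 500
    alpha: float = 0.01
    bonferroni_m: Optional[int] = None  # default: comparisons in this run
    master_seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "AnalysisConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _load_query(path: str, cfg: AnalysisConfig) -> IntervalSet:
    qset = read_bed(path)
    n_raw = len(qset)
    if cfg.length_cutoff is not None:
        qset = filter_by_length(qset, cfg.length_cutoff)
    n_len = len(qset)
    if cfg.deoverlap:
        qset = select_smallest_nonoverlapping(qset)
    logger.info("query %s: %d raw, %d after length filter, %d after de-overlap",
                qset.label, n_raw, n_len, len(qset))
    return qset


def run_compare(cfg: AnalysisConfig,
                queries: Optional[Sequence[IntervalSet]] = None,
                references: Optional[Sequence[IntervalSet]] = None,
                genome: Optional[GenomeSpec] = None) -> pd.DataFrame:
    """All query x reference comparisons with permutation significance.

    In-memory sets may be passed directly (the analysis scripts do); paths
    in the config are loaded otherwise. Writes ``compare_report.tsv`` and a
    JSON twin, one row per pair; a failing pair is logged and skipped, the
    run continues.
    """
    if genome is None:
        genome = read_genome(cfg.genome_path)
    if queries is None:
        queries = [_load_query(p, cfg) for p in cfg.query_paths]
    if references is None:
        references = [read_bed(p) for p in cfg.reference_paths]

    n_comparisons = len(queries) * len(references)
    m = cfg.bonferroni_m if cfg.bonferroni_m is not None else max(n_comparisons, 1)
    alpha_adj = bonferroni_alpha(cfg.alpha, m)
    logger.info("compare: %d pairs, n_perm=%d, adjusted alpha=%.3g, seed=%d",
                n_comparisons, cfg.n_perm, alpha_adj, cfg.master_seed)

    rows: List[Dict] = []
    for qi, qset in enumerate(queries):
        for ri, ref in enumerate(references):
            pair_seed = int(np.random.SeedSequence(
                entropy=cfg.master_seed, spawn_key=(qi, ri)).generate_state(1)[0])
            try:
                index = ReferenceIndex(ref)
                obs = count_overlapping(qset, index)
                perm = permutation_test(
                    qset, index, genome, n_perm=cfg.n_perm,
                    rng_seed=pair_seed, alpha_adjusted=alpha_adj)
            except ValueError as exc:
                logger.warning("pair (%s, %s) skipped: %s",
                               qset.label, ref.label, exc)
                continue
            rows.append({
                "query_label": qset.label,
                "reference_label": ref.label,
                "n_query": obs.n_query,
                "n_overlapping": obs.n_overlapping,
                "fraction_pct": percent(obs.n_overlapping, obs.n_query),
                "perm_mean": round(perm.perm_mean, 6),
                "perm_sd": round(perm.perm_sd, 6),
                "z": round(perm.z, 6) if perm.z is not None else None,
                "p_two_tailed": (float(f"{perm.p_two_tailed:.6g}")
                                 if perm.p_two_tailed is not None else None),
                "alpha_adjusted": float(f"{alpha_adj:.6g}"),
                "classification": perm.classification,
            })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    _write_report(report, cfg.outdir, "compare_report")
    return report


def run_correlate(cfg: AnalysisConfig,
                  query: Optional[IntervalSet] = None,
                  references: Optional[Sequence[IntervalSet]] = None
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Found-vector correlation matrix + per-batch-pair summary table.

    References need batch labels (from config ``batch_labels`` parallel to
    ``reference_paths``, or from each set's ``metadata['batch']``). Writes
    ``correlation_matrix.tsv``, ``batches.tsv`` and ``batch_summary.tsv``.
    """
    if query is None:
        query = _load_query(cfg.query_paths[0], cfg)
    if references is None:
        references = [read_bed(p) for p in cfg.reference_paths]
        if cfg.batch_labels:
            for ref, batch in zip(references, cfg.batch_labels):
                ref.metadata["batch"] = batch
    if len(references) < 2:
        raise ValueError("correlation analysis needs >= 2 reference sets")

    vectors = [
        found_vector(query, ref, batch_label=str(ref.metadata.get("batch", "")))
        for ref in references
    ]
    non_constant = sum(1 for v in vectors if 0 < v.n_found < len(v.values))
    if non_constant < 2:
        raise ValueError("fewer than 2 non-constant found-vectors")
    matrix = correlation_matrix(vectors)

    os.makedirs(cfg.outdir, exist_ok=True)
    export_matrix(matrix,
                  os.path.join(cfg.outdir, "correlation_matrix.tsv"),
                  batch_path=os.path.join(cfg.outdir, "batches.tsv"))

    batches = sorted(set(matrix.batches))
    rows: List[Dict] = []
    for i, a in enumerate(batches):
        for b in batches[i:]:
            try:
                mean_r, sd_r, n_pairs = group_summary(matrix, a, b)
                rows.append({"batch_a": a, "batch_b": b,
                             "mean_r": round(mean_r, 6),
                             "sd_r": round(sd_r, 6), "n_pairs": n_pairs})
            except ValueError as exc:
                logger.warning("batch pair (%s, %s): %s", a, b, exc)
                rows.append({"batch_a": a, "batch_b": b, "mean_r": None,
                             "sd_r": None, "n_pairs": 0})
    summary = pd.DataFrame(rows, columns=["batch_a", "batch_b", "mean_r",
                                          "sd_r", "n_pairs"])
    summary.to_csv(os.path.join(cfg.outdir, "batch_summary.tsv"),
                   sep="\t", index=False, na_rep="NA")
    frame = matrix.to_frame()
    return frame, summary


def run_simulate(cfg: AnalysisConfig,
                 world_config: Optional[SyntheticWorldConfig] = None) -> Dict[str, str]:
    """Generate the synthetic world and export the re-loadable bundle."""
    if world_config is None:
        world_config = default_config(master_seed=cfg.master_seed)
    world = make_world(world_config)
    paths = export_world(world, cfg.outdir)
    logger.info("simulate: %d true enhancers, %d reporter intervals, %d assay sets",
                len(world.true_enhancers), len(world.reporter_set),
                len(world.assay_sets))
    return paths


def _write_report(report: pd.DataFrame, outdir: str, stem: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    report.to_csv(os.path.join(outdir, f"{stem}.tsv"), sep="\t",
                  index=False, na_rep="NA")
    with open(os.path.join(outdir, f"{stem}.json"), "wt", encoding="utf-8") as fh:
        json.dump(report.to_dict(orient="records"), fh, indent=2, sort_keys=True)
        fh.write("\n")
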