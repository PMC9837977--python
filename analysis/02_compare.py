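#!/usr/bin/env python
"""Pairwise reporter-vs-assay overlap with permutation significance.

Loads the exported world bundle, counts single-basepair overlaps for each
reporter-vs-assay pair (``-wa -u`` semantics), runs a 500-permutation
genome-shuffle z-test per pair at a Bonferroni-adjusted alpha of
0.01 / n_pairs, and reports overlap percentages and enrichment calls.
"""

import argparse
import os

from enhconcord import AnalysisConfig, read_bed, read_genome, run_compare


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--world", default="results/world")
    ap.add_argument("--outdir", default="results/compare")
    ap.add_argument("--n-perm", type=int, default=500)
    args = ap.parse_args()

    genome = read_genome(os.path.join(args.world, "genome.chrom.sizes"))
    reporter = read_bed(os.path.join(args.world, "reporter.bed"), "reporter")
    refs = [read_bed(os.path.join(args.world, f), f[:-4])
            for f in sorted(os.listdir(args.world))
            if f.startswith("series") and f.endswith(".bed")]

    cfg = AnalysisConfig(n_perm=args.n_perm, master_seed=args.seed,
                         outdir=args.outdir)
    report = run_compare(cfg, queries=[reporter], references=refs,
                         genome=genome)
    n_sig = int((report["classification"] == "enriched").sum())
    print(report.to_string(index=False))
    print(f"\n{n_sig}/{len(report)} assay sets significantly enriched; "
          f"median overlap {report['fraction_pct'].median():.0f}% "
          f"(range {report['fraction_pct'].min()}-{report['fraction_pct'].max()}%)")
    print(f"report written to {args.outdir}/compare_report.tsv")


if __name__ == "__main__":
    main()
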