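#!/usr/bin/env python
"""Generate the synthetic study world and export it as a BED bundle.

The world emulates the study design: a ground-truth enhancer universe on a
small two-chromosome genome, a reporter-style query set with partial
sensitivity, boundary jitter and off-truth false positives, and two
experiment series ("seriesA", "seriesB") of five chromatin-assay-style
sets each, with disjoint latent detectable subsets of the truth.
"""

import argparse

from enhconcord import AnalysisConfig, run_simulate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/world")
    args = ap.parse_args()

    paths = run_simulate(AnalysisConfig(master_seed=args.seed,
                                        outdir=args.outdir))
    n_bed = sum(1 for p in paths if p.endswith(".bed"))
    print(f"world exported to {args.outdir}: {n_bed} BED sets "
          f"(truth + reporter + 10 assays), chrom.sizes, truth table, config")


if __name__ == "__main__":
    main()
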