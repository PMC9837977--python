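# Methods

## Coordinate model

All intervals are BED-standard 0-based half-open `[start, end)`; an
interval of length L covers bases `start … start+L−1`. Two intervals
overlap iff they share at least one base: `a.start < b.end and
b.start < a.end` on the same chromosome. Adjacency (`end == start`) is not
overlap. Strand is ignored: the comparisons operate purely on genomic
position. Zero-length intervals are rejected at parse time rather than
silently dropped, and BED columns beyond the name are carried in metadata
but never used.

## Overlap counting

`count_overlapping` implements unique-query reporting (`-wa -u`): each
query interval contributes at most 1 to the count, regardless of how many
reference intervals it touches. The engine merges the reference per
chromosome into disjoint sorted spans and answers each query with one
binary search (the last span starting before the query's end overlaps it
iff that span ends after the query's start); this is O((n+m) log m) and
is validated in the test suite against both a brute-force all-pairs
oracle and `bedtools intersect -wa -u` on random fixtures. Overlap
fractions reported in summaries are rounded half-away-from-zero to
integer percent, matching the conventional presentation of such results.

## Shuffle null and permutation z-test

Significance of an observed overlap count is assessed against a null in
which each query interval is independently relocated to a uniformly
random valid position genome-wide: for a length-L interval every
`(chrom, start)` with `start + L ≤ chrom_length` is equally likely, so
longer chromosomes receive proportionally more placements. Shuffled
intervals may overlap one another; no exclusion or GC/length matching is
applied. Per-chromosome shuffling is deliberately not the default — the
genome-wide scheme is the simplest null consistent with "anywhere the
interval fits".

With `n_perm` permutations (default 500) the observed count is reduced to

    z = (observed − mean(perm)) / sd(perm),   sd with n−1 denominator,

and a two-tailed p-value `2·(1 − Φ(|z|))` under the normal approximation.
The normal approximation is used rather than the empirical permutation
tail because Bonferroni-level thresholds (e.g. 0.01/21 ≈ 4.8·10⁻⁴) are
finer than 1/n_perm can resolve. If the permuted counts are constant
(sd = 0, e.g. a reference tiling the genome) the result is flagged
`degenerate` with z and p unset rather than ±∞. Classification at the
adjusted threshold α/m distinguishes `enriched` (p < α/m, z > 0) from
`depleted` (p < α/m, z < 0); m defaults to the number of comparisons in
the invoked run and is configurable for cross-run families.

Permutation i draws its seed from `SeedSequence(master_seed, spawn_key=(i,))`,
so results are reproducible and independent of execution order. The
internal permutation loop works on coordinate arrays directly; a test
pins it to the public `shuffle_set` route (identical counts, same seeds).
Null calibration (500 replicate true-null datasets, 200 intervals per
set on a 2 × 1 Mb genome, n_perm = 200) confirms z has mean ≈ 0 and
sd ≈ 1 and that rejections at α/m occur at the nominal rate.

## Set construction

- **Length filter**: inclusive (`length ≤ cutoff`), so a 2000 bp interval
  survives a 2000 bp cutoff. Typical reporter-tested fragments can be
  arbitrarily long; the cutoff guards against fragments spanning several
  independent elements.
- **Smallest-feature de-overlap**: intervals are visited in order of
  (length ascending, chrom, start, name) and accepted iff they overlap no
  previously accepted interval. The greedy rule is deterministic,
  idempotent, keeps the smallest member of any overlapping cluster, and
  returns a pairwise non-overlapping subset. A globally optimal
  (maximum-independent-set) variant would differ on some tangled
  clusters; greedy is the fixed, documented choice.
- **Tissue grouping**: an interval joins every group that any of its
  annotation terms maps to; unmapped terms are ignored, unknown interval
  names warn and skip, empty groups are dropped.
- **Consensus merge**: per-base support counts each track once (a track's
  internally overlapping intervals are unioned first); consensus = maximal
  runs with support ≥ ceil(f·n_tracks). The ceiling matters: "at least
  50 %" of 3 tracks means 2, not 1. Implemented as a breakpoint sweep, so
  cost is independent of genome length; tests pin it to a per-base
  counter on a tiny genome and to track-order invariance.

## Found-vector correlation

For a fixed query set, each reference yields a 0/1 vector in the query's
deterministic order; entry i is 1 iff query interval i hits the
reference. Pairwise Pearson correlation on binary vectors equals the phi
coefficient of the 2×2 contingency table, which a test verifies
algebraically. Constant vectors have undefined correlation; those entries
are marked NaN and excluded from summaries — coercing them to 0 would
bias group means. Batch summaries report mean and sample sd over
off-diagonal within-batch pairs, or all cross pairs between batches;
the sd over a single pair is reported as 0. Pearson is the default (and
the only tested) correlation; Spearman on 0/1 vectors would be a
monotone transform of the same information.

## Synthetic world generator

The generator emulates the study design with known parameters:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 1 Mb | two chromosomes, chrom.sizes-compatible |
| n_true | 500 | non-overlapping true enhancers |
| length_range | 100–1000 bp | uniform lengths; enhancers are typically hundreds of bp |
| reporter sensitivity s_r | 0.7 | P(true enhancer enters the reporter query) |
| reporter false positives | 150 | intervals placed wholly off-truth |
| boundary jitter | ±40 bp | uniform, endpoints independent; reporter fragment ends rarely match the functional element exactly |
| batches | 2 × 5 assays | two experiment series |
| latent fraction q | 0.4 per batch | share of truth detectable by the series (disjoint between series by default) |
| assay sensitivity s_a | 0.9 | P(detectable enhancer appears in one assay) |
| assay false positives | 100 | off-truth intervals per assay |

Defaults are chosen so the generated data sit in the regime the analyses
target: per-assay found fractions in the tens of percent, strongly
enriched over the null, with clean series-driven correlation structure.
All randomness derives from a master seed through per-stage
`SeedSequence` spawns, so identical configs give byte-identical worlds
and changing one stage's parameters does not perturb the others.

False positives avoid the truth entirely, keeping the
sensitivity/false-positive decomposition exact for the closed-form
oracle: with no false positives the expected reporter-vs-assay found
fraction is 100·q·s_a; with them, a mixture term approximates
false-positive collisions by the assay's genomic footprint. Jitter is
clamped to the chromosome and to minimum length 1; because the default
jitter is below half the minimum enhancer length, a jittered true
positive always still overlaps its source enhancer, which the closed
form assumes.

What the generator does **not** emulate: read-level signal, peak shapes,
non-uniform genomic backgrounds (GC, mappability, gaps), correlated
false positives between assays, and length/position biases of real peak
callers. Passing tests therefore demonstrate correctness and calibration
of the *statistics* on interval data, not robustness to every artefact
of real chromatin assays.

## Problem sizes

The test and acceptance workloads use 200–500 intervals per set on 1–2 Mb
genomes, 100–500 permutations, and 25–100 replicate seeds per experiment
— sizes at which Monte-Carlo error is small relative to the asserted
effects while the full suite completes in well under a minute of compute
for the unit tests and a few tens of seconds for the acceptance checks.

## Known limitations

- The normal approximation of the permutation p-value is inaccurate in
  the extreme tails when permuted counts are small and skewed; degenerate
  and near-degenerate references should be inspected via the permuted
  counts themselves (`keep_counts=True`).
- The greedy smallest-feature rule is one fixed resolution of overlap
  clusters; alternatives exist and would change set sizes slightly.
- The Bonferroni family m is a per-run choice; combining runs into one
  family must be done explicitly via `bonferroni_m`.
- Heatmap rendering is cosmetic and untested.
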