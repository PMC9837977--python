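"""Overlap engine, shuffle null, permutation z-test, classification."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhconcord import (
    GenomeSpec,
    Interval,
    IntervalSet,
    OverlapResult,
    bonferroni_alpha,
    classify,
    count_overlapping,
    percent,
    permutation_test,
    select_best_matching,
    shuffle_set,
    write_bed,
)
from enhconcord.overlap import (
    DEGENERATE,
    DEPLETED,
    ENRICHED,
    NOT_SIGNIFICANT,
    PermutationResult,
    ReferenceIndex,
    derive_seed,
)
from enhconcord.synthetic import place_avoiding

from conftest import brute_force_overlap_count, random_interval_set


class TestCountOverlapping:
    def test_query_spanning_two_references_counted_once(self):
        q = IntervalSet("q", [Interval("chr1", 0, 1000, "big")])
        r = IntervalSet("r", [Interval("chr1", 100, 200, "a"),
                              Interval("chr1", 700, 800, "b")])
        res = count_overlapping(q, r)
        assert res.n_overlapping == 1  # -u: unique reporting
        assert res.found_names == ["big"]

    def test_disjoint_chromosomes(self):
        q = IntervalSet("q", [Interval("chr1", 0, 100, "a")])
        r = IntervalSet("r", [Interval("chr2", 0, 100, "b")])
        assert count_overlapping(q, r).n_overlapping == 0

    def test_empty_query_errors(self):
        with pytest.raises(ValueError):
            count_overlapping(IntervalSet("q", []), IntervalSet("r", []))

    def test_empty_reference_gives_zero(self):
        q = IntervalSet("q", [Interval("chr1", 0, 100, "a")])
        res = count_overlapping(q, IntervalSet("r", []))
        assert res.n_overlapping == 0 and res.fraction_pct == 0.0

    @given(st.integers(0, 2**32 - 1), st.integers(1, 300), st.integers(1, 300))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed, n, m):
        rng = np.random.default_rng(seed)
        g = GenomeSpec({"chr1": 20_000, "chr2": 10_000})
        q = random_interval_set(rng, g, n, "q", min_len=5, max_len=500)
        r = random_interval_set(rng, g, m, "r", min_len=5, max_len=500)
        res = count_overlapping(q, r)
        assert sorted(res.found_names) == sorted(brute_force_overlap_count(q, r))

    def test_reference_superset_monotone(self):
        rng = np.random.default_rng(5)
        g = GenomeSpec({"chr1": 50_000})
        q = random_interval_set(rng, g, 100, "q")
        r_small = random_interval_set(rng, g, 50, "r")
        extra = random_interval_set(rng, g, 50, "extra")
        r_big = IntervalSet("rbig", list(r_small) + list(extra))
        assert (count_overlapping(q, r_big).n_overlapping
                >= count_overlapping(q, r_small).n_overlapping)


@pytest.mark.skipif(shutil.which("bedtools") is None,
                    reason="bedtools not on PATH")
def test_count_matches_bedtools_intersect_wa_u(tmp_path):
    """Independent oracle: bedtools intersect -wa -u on a random fixture."""
    rng = np.random.default_rng(42)
    g = GenomeSpec({"chr1": 100_000, "chr2": 50_000})
    q = random_interval_set(rng, g, 200, "q", min_len=20, max_len=900)
    r = random_interval_set(rng, g, 300, "r", min_len=20, max_len=900)
    qp, rp = tmp_path / "q.bed", tmp_path / "r.bed"
    write_bed(q, qp)
    write_bed(r, rp)
    out = subprocess.run(
        ["bedtools", "intersect", "-wa", "-u", "-a", str(qp), "-b", str(rp)],
        capture_output=True, text=True, check=True,
    )
    bedtools_names = sorted(line.split("\t")[3]
                            for line in out.stdout.strip().splitlines() if line)
    res = count_overlapping(q, r)
    assert sorted(res.found_names) == bedtools_names


class TestPercent:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(8779, 11549, 76), (6027, 7527, 80), (5, 21, 24), (10, 21, 48),
         (4, 11, 36), (45, 56, 80), (0, 10, 0), (1, 2, 50), (3, 8, 38)],
    )
    def test_rounding(self, num, den, expected):
        assert percent(num, den) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent(1, 0)


class TestShuffle:
    def test_forced_placement(self):
        # one chromosome of length L, one interval of length L: start must be 0
        g = GenomeSpec({"only": 70})
        s = IntervalSet("q", [Interval("only", 0, 70, "x")])
        out = shuffle_set(s, g, rng_seed=3)
        assert [(iv.start, iv.end) for iv in out] == [(0, 70)]

    @pytest.mark.parametrize("seed", range(15))
    def test_lengths_names_preserved_and_in_bounds(self, seed, genome):
        rng = np.random.default_rng(seed)
        s = random_interval_set(rng, genome, 50, "q")
        out = shuffle_set(s, genome, rng_seed=seed)
        assert sorted(iv.length for iv in out) == sorted(iv.length for iv in s)
        assert sorted(out.names) == sorted(s.names)
        assert all(genome.contains(iv) for iv in out)

    def test_deterministic_given_seed(self, genome):
        rng = np.random.default_rng(0)
        s = random_interval_set(rng, genome, 40, "q")
        a = shuffle_set(s, genome, rng_seed=11)
        b = shuffle_set(s, genome, rng_seed=11)
        assert [iv.sort_key() for iv in a] == [iv.sort_key() for iv in b]

    def test_interval_longer_than_any_chromosome(self, tiny_genome):
        s = IntervalSet("q", [Interval("chrA", 0, 999, "x")])
        g = GenomeSpec({"chrA": 500})
        with pytest.raises(ValueError):
            shuffle_set(s, g, rng_seed=1)


class TestPermutationTest:
    def test_fast_path_matches_object_path(self, genome):
        """Internal vectorised permutation counts equal counts obtained by
        shuffling via the public API with the same derived seeds."""
        rng = np.random.default_rng(1)
        q = random_interval_set(rng, genome, 60, "q")
        r = random_interval_set(rng, genome, 80, "r")
        res = permutation_test(q, r, genome, n_perm=20, rng_seed=99,
                               keep_counts=True)
        expected = [
            count_overlapping(shuffle_set(q, genome, derive_seed(99, i)), r).n_overlapping
            for i in range(1, 21)
        ]
        assert res.perm_counts.tolist() == expected

    def test_degenerate_when_reference_tiles_genome(self):
        g = GenomeSpec({"chr1": 1000})
        q = IntervalSet("q", [Interval("chr1", 10, 50, "a"),
                              Interval("chr1", 500, 600, "b")])
        r = IntervalSet("r", [Interval("chr1", 0, 1000, "all")])
        res = permutation_test(q, r, g, n_perm=10, rng_seed=0)
        assert res.classification == DEGENERATE
        assert res.z is None and res.p_two_tailed is None

    def test_z_centering(self):
        res = PermutationResult(observed=10, n_perm=100, perm_mean=10.0,
                                perm_sd=2.0, z=0.0, p_two_tailed=1.0,
                                alpha_adjusted=0.01, classification="")
        assert classify(res, 0.01) == NOT_SIGNIFICANT

    def test_n_perm_too_small(self, genome):
        q = IntervalSet("q", [Interval("chr1", 0, 100, "a")])
        with pytest.raises(ValueError):
            permutation_test(q, q, genome, n_perm=1, rng_seed=0)

    def test_planted_query_enriched(self, genome):
        rng = np.random.default_rng(7)
        r = random_interval_set(rng, genome, 150, "r", min_len=200, max_len=900)
        planted = [Interval(iv.chrom, iv.start + 10, iv.end - 10, f"p{k}")
                   for k, iv in enumerate(list(r)[:100])]
        q = IntervalSet("q", planted)
        res = permutation_test(q, r, genome, n_perm=100, rng_seed=3,
                               alpha_adjusted=1e-3)
        assert res.z > 0 and res.classification == ENRICHED

    def test_avoiding_query_depleted(self, genome):
        rng = np.random.default_rng(8)
        r = random_interval_set(rng, genome, 300, "r", min_len=400, max_len=900)
        q = IntervalSet("q", place_avoiding(genome, r, 150, (100, 500), rng))
        res = permutation_test(q, r, genome, n_perm=100, rng_seed=4,
                               alpha_adjusted=1e-3)
        assert res.z < 0 and res.classification == DEPLETED

    def test_null_z_roughly_standard(self, genome):
        """Small qualitative null check; the full 500-replicate calibration
        runs in the acceptance suite."""
        rng = np.random.default_rng(12)
        zs = []
        for rep in range(40):
            q = random_interval_set(rng, genome, 150, "q")
            r = random_interval_set(rng, genome, 150, "r")
            zs.append(permutation_test(q, r, genome, n_perm=100,
                                       rng_seed=rep).z)
        assert abs(np.mean(zs)) < 0.5
        assert 0.6 < np.std(zs) < 1.6


class TestClassification:
    def test_bonferroni(self):
        assert bonferroni_alpha(0.01, 21) == pytest.approx(0.01 / 21)
        assert bonferroni_alpha(0.01, 1) == 0.01
        assert bonferroni_alpha(0.01, 56) == pytest.approx(0.01 / 56)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.01, 0)

    @pytest.mark.parametrize(
        "z,p,expected",
        [(5.0, 1e-7, ENRICHED), (-5.0, 1e-7, DEPLETED),
         (1.0, 0.317, NOT_SIGNIFICANT)],
    )
    def test_classify(self, z, p, expected):
        res = PermutationResult(observed=0, n_perm=100, perm_mean=0.0,
                                perm_sd=1.0, z=z, p_two_tailed=p,
                                alpha_adjusted=4.76e-4, classification="")
        assert classify(res, 4.76e-4) == expected


class TestSelectBestMatching:
    def _res(self, n_ov, n_q=100):
        return OverlapResult("q", "r", n_q, n_ov)

    def test_argmax(self):
        assert select_best_matching({"A": self._res(10), "B": self._res(26)}) == "B"

    def test_tie_breaks_lexicographically(self):
        assert select_best_matching({"B": self._res(26), "A": self._res(26)}) == "A"

    def test_single_and_empty(self):
        assert select_best_matching({"only": self._res(3)}) == "only"
        with pytest.raises(ValueError):
            select_best_matching({})
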