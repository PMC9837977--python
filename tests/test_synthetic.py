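"""Synthetic world generation: ground truth, recoverability, determinism."""

import numpy as np
import pytest
from scipy import stats

from enhconcord import (
    BatchConfig,
    GenomeSpec,
    ReporterConfig,
    SyntheticWorldConfig,
    correlation_matrix,
    count_overlapping,
    default_config,
    expected_overlap_fraction,
    found_vector,
    group_by_tissue,
    group_summary,
    intervals_overlap,
    make_tissue_world,
    make_world,
)
from enhconcord.synthetic import export_world


def small_config(seed=0, **kw):
    defaults = dict(
        genome=GenomeSpec({"chr1": 500_000, "chr2": 500_000}),
        n_true=200,
        length_range=(100, 600),
        reporter=ReporterConfig(sensitivity=0.7, n_false_positives=50,
                                boundary_jitter_bp=30),
        batches=[BatchConfig("A", latent_fraction=0.4, n_assays=3,
                             assay_sensitivity=0.9, assay_fp_count=40),
                 BatchConfig("B", latent_fraction=0.4, n_assays=3,
                             assay_sensitivity=0.9, assay_fp_count=40)],
        master_seed=seed,
    )
    defaults.update(kw)
    return SyntheticWorldConfig(**defaults)


class TestMakeWorld:
    def test_truth_nonoverlapping_and_in_bounds(self):
        w = make_world(small_config(1))
        ivs = list(w.true_enhancers)
        for i, a in enumerate(ivs):
            for b in ivs[i + 1:]:
                assert not intervals_overlap(a, b)
        assert all(w.genome.contains(iv) for iv in ivs)

    def test_degenerate_reporter_equals_truth(self):
        cfg = small_config(2, reporter=ReporterConfig(
            sensitivity=1.0, n_false_positives=0, boundary_jitter_bp=0))
        w = make_world(cfg)
        assert [iv.sort_key() for iv in w.reporter_set] == [
            iv.sort_key() for iv in w.true_enhancers]

    def test_reporter_size_within_binomial_ci(self):
        """|reporter TPs| across seeds tracks Binomial(n_true, s_r)."""
        n_true, s_r = 200, 0.6
        sizes = []
        for seed in range(30):
            cfg = small_config(seed, n_true=n_true,
                               reporter=ReporterConfig(sensitivity=s_r,
                                                       n_false_positives=0,
                                                       boundary_jitter_bp=0))
            sizes.append(len(make_world(cfg).reporter_set))
        mean = np.mean(sizes)
        se = np.sqrt(n_true * s_r * (1 - s_r)) / np.sqrt(30)
        assert abs(mean - n_true * s_r) < 3.5 * se

    def test_false_positives_avoid_truth(self):
        w = make_world(small_config(3))
        truth = list(w.true_enhancers)
        fps = [iv for iv in w.reporter_set if iv.name.startswith("reporter_fp")]
        assert len(fps) == 50
        for fp in fps:
            assert not any(intervals_overlap(fp, t) for t in truth)

    def test_truth_table_consistent_with_membership(self):
        w = make_world(small_config(4))
        for aset in w.assay_sets:
            member_names = {iv.name for iv in aset}
            col = w.truth_table[aset.label]
            for name, present in col.items():
                assert present == (name in member_names)

    def test_disjoint_latent_subsets(self):
        w = make_world(small_config(5))
        a = set(w.latent_subsets["A"])
        b = set(w.latent_subsets["B"])
        assert not (a & b)
        assert len(a) == len(b) == round(0.4 * 200)

    def test_deterministic_given_seed(self, tmp_path):
        w1 = make_world(small_config(6))
        w2 = make_world(small_config(6))
        p1 = export_world(w1, tmp_path / "a")
        p2 = export_world(w2, tmp_path / "b")
        for name in p1:
            assert open(p1[name], "rb").read() == open(p2[name], "rb").read()

    def test_infeasible_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticWorldConfig(genome=GenomeSpec({"chr1": 1000}),
                                 n_true=100, length_range=(100, 600))


class TestBatchStructure:
    def test_within_batch_correlation_exceeds_between(self):
        w = make_world(small_config(7))
        vecs = [found_vector(w.reporter_set, a, batch_label=a.metadata["batch"])
                for a in w.assay_sets]
        m = correlation_matrix(vecs)
        within_a, _, _ = group_summary(m, "A")
        within_b, _, _ = group_summary(m, "B")
        between, _, _ = group_summary(m, "A", "B")
        assert within_a > between and within_b > between


class TestExpectedOverlapFraction:
    def test_perfect_detection(self):
        cfg = small_config(
            0,
            reporter=ReporterConfig(1.0, 0, 0),
            batches=[BatchConfig("A", latent_fraction=1.0, n_assays=1,
                                 assay_sensitivity=1.0, assay_fp_count=0)],
        )
        assert expected_overlap_fraction(cfg) == pytest.approx(100.0)

    def test_product_of_probabilities(self):
        cfg = small_config(
            0,
            reporter=ReporterConfig(0.7, 0, 0),
            batches=[BatchConfig("A", latent_fraction=0.5, n_assays=1,
                                 assay_sensitivity=0.8, assay_fp_count=0)],
        )
        assert expected_overlap_fraction(cfg) == pytest.approx(40.0)

    def test_full_mixture_matches_monte_carlo(self):
        """Closed-form mixture vs simulation, within Monte-Carlo error."""
        fractions = []
        for seed in range(40):
            cfg = small_config(seed)
            w = make_world(cfg)
            res = count_overlapping(w.reporter_set, w.assay_sets[0])
            fractions.append(res.fraction_pct)
        mc_mean = np.mean(fractions)
        mc_se = stats.sem(fractions)
        expect = expected_overlap_fraction(small_config(0))
        # FP collision term is an approximation; allow 2 sd + 1 point slack
        assert abs(mc_mean - expect) < 2 * mc_se + 1.0


class TestTissueWorld:
    def test_single_tissue_contains_all(self):
        tw = make_tissue_world(small_config(8), n_tissues=1)
        assert sorted(tw.groups["tissue_1"]) == sorted(
            tw.world.true_enhancers.names)

    def test_disjoint_partition_sums_to_n_true(self):
        tw = make_tissue_world(small_config(9), n_tissues=3)
        sizes = sum(len(v) for v in tw.groups.values())
        assert sizes == 200

    def test_roundtrip_through_group_by_tissue(self):
        tw = make_tissue_world(small_config(10), n_tissues=3,
                               shared_fraction=0.2)
        groups = group_by_tissue(tw.world.true_enhancers, tw.annotations,
                                 tw.tissue_map)
        assert set(groups) == set(tw.groups)
        for g in groups:
            assert sorted(groups[g].names) == sorted(tw.groups[g])
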