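"""Stratified similarity splitting, verification and negative sampling."""

import numpy as np
import pytest

from enzrxn.similarity import SimilarityMatrix
from enzrxn.splitting import (
    SplitCollapseError,
    SplitConfig,
    cluster_at_bound,
    misassignment_bound,
    sample_negatives,
    stratified_similarity_split,
    verify_split,
)


def block_matrix(block_sizes, within=1.0, cross=0.0):
    n = sum(block_sizes)
    s = np.full((n, n), cross)
    off = 0
    for b in block_sizes:
        s[off : off + b, off : off + b] = within
        off += b
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix([f"e{i}" for i in range(n)], s, "rcmcs")


def planted_three_level(n_per=10, seed=7):
    """Blocks at three similarity levels: 0.9 within, 0.5 between block pairs, 0.1 else."""
    rng = np.random.default_rng(seed)
    n = 6 * n_per
    s = np.full((n, n), 0.1)
    for g in range(3):  # superblocks of two blocks each
        lo, hi = 2 * g * n_per, 2 * (g + 1) * n_per
        s[lo:hi, lo:hi] = 0.5
    for b in range(6):
        lo, hi = b * n_per, (b + 1) * n_per
        s[lo:hi, lo:hi] = 0.9
    s += rng.uniform(-0.02, 0.02, size=(n, n))
    s = np.clip((s + s.T) / 2, 0, 1)
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix([f"e{i}" for i in range(n)], s, "rcmcs")


class TestClustering:
    def test_two_blocks_two_clusters(self):
        m = block_matrix([5, 5])
        assert len(cluster_at_bound(m, 0.5)) == 2

    def test_bound_one_all_singletons(self):
        m = block_matrix([4, 4], within=0.9)
        assert len(cluster_at_bound(m, 1.0)) == 8

    def test_single_linkage_transitivity(self):
        s = np.eye(3)
        s[0, 1] = s[1, 0] = 0.7
        s[1, 2] = s[2, 1] = 0.7
        s[0, 2] = s[2, 0] = 0.1
        m = SimilarityMatrix(list("abc"), s, "rcmcs")
        clusters = cluster_at_bound(m, 0.6)
        assert sorted(map(sorted, clusters)) == [[0, 1, 2]]

    def test_cross_cluster_similarity_below_bound(self):
        m = planted_three_level()
        for bound in (0.3, 0.7):
            clusters = cluster_at_bound(m, bound)
            labels = {}
            for k, cl in enumerate(clusters):
                for i in cl:
                    labels[i] = k
            n = len(m.ids)
            for i in range(n):
                for j in range(i + 1, n):
                    if labels[i] != labels[j]:
                        assert m.scores[i, j] < bound


class TestStratifiedSplit:
    def test_whole_cluster_sampled(self):
        m = block_matrix([5, 5, 5, 5])
        cfg = SplitConfig(bounds=(0.5, 1.0), test_fraction=0.25,
                          quota_fractions=(0.25, 0.0), seed=3)
        a = stratified_similarity_split(m, cfg)
        test = a.test_ids()
        assert len(test) == 5
        blocks = {int(t[1:]) // 5 for t in test}
        assert len(blocks) == 1  # exactly one whole cluster

    def test_all_similar_matrix_collapses_at_first_bound(self):
        s = np.full((10, 10), 0.99)
        np.fill_diagonal(s, 1.0)
        m = SimilarityMatrix([f"x{i}" for i in range(10)], s, "gsi")
        with pytest.raises(SplitCollapseError) as exc:
            stratified_similarity_split(m, SplitConfig(bounds=(0.4, 1.0), seed=0))
        assert exc.value.bound == 0.4

    def test_realized_strata_verified_on_planted_structure(self):
        m = planted_three_level()
        cfg = SplitConfig(bounds=(0.3, 0.7, 1.0), test_fraction=0.3,
                          quota_fractions=(0.1, 0.1, 0.1), seed=5)
        a = stratified_similarity_split(m, cfg)
        report = verify_split(a, m)
        assert report.all_pass
        assert sum(report.stratum_counts.values()) == len(a.test_ids())

    def test_partition_and_cv_fold_coverage(self):
        m = planted_three_level(seed=9)
        cfg = SplitConfig(bounds=(0.3, 0.7, 1.0), test_fraction=0.3,
                          quota_fractions=(0.1, 0.1, 0.1), cv_folds=3, seed=1)
        a = stratified_similarity_split(m, cfg)
        assert sorted(a.entity_ids) == sorted(m.ids)
        folds = [a.entries[e].fold for e in a.entity_ids]
        assert set(folds) == {"test", "trainval"}
        cv = [a.entries[e].cv_fold for e in a.trainval_ids()]
        assert set(cv) == {0, 1, 2}

    def test_deterministic_given_seed(self):
        m = planted_three_level(seed=2)
        cfg = SplitConfig(bounds=(0.3, 0.7, 1.0), test_fraction=0.3,
                          quota_fractions=(0.1, 0.1, 0.1), seed=42)
        a1 = stratified_similarity_split(m, cfg)
        a2 = stratified_similarity_split(m, cfg)
        assert a1.to_rows() == a2.to_rows()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="ascending"):
            SplitConfig(bounds=(0.6, 0.4, 1.0))
        with pytest.raises(ValueError, match="sum"):
            SplitConfig(bounds=(0.5, 1.0), test_fraction=0.2,
                        quota_fractions=(0.3, 0.3))


class TestVerifySplit:
    def test_corrupted_assignment_detected(self):
        m = planted_three_level(seed=4)
        cfg = SplitConfig(bounds=(0.3, 0.7, 1.0), test_fraction=0.3,
                          quota_fractions=(0.1, 0.1, 0.1), seed=8)
        a = stratified_similarity_split(m, cfg)
        assert verify_split(a, m).all_pass
        # swap one low-similarity test entity's stratum label downward
        victim = next(
            e for e in a.test_ids()
            if a.entries[e].declared_stratum[0] > 0
        )
        a.entries[victim].declared_stratum = (0.0, 0.05)
        report = verify_split(a, m)
        assert report.n_violations == 1
        failing = [row for row in report.per_entity if not row["pass"]]
        assert failing[0]["entity_id"] == victim


class TestNegativeSampling:
    @pytest.fixture()
    def setup(self):
        m = block_matrix([5, 5, 5, 5])
        cfg = SplitConfig(bounds=(0.5, 1.0), test_fraction=0.25,
                          quota_fractions=(0.25, 0.0), cv_folds=3, seed=3)
        a = stratified_similarity_split(m, cfg)
        reactions = list(m.ids)
        proteins = [f"p{i}" for i in range(20)]
        positives = [(f"p{i}", f"e{i}") for i in range(20)]
        return a, proteins, reactions, positives

    def test_ratios_exact_and_disjoint_from_positives(self, setup):
        a, proteins, reactions, positives = setup
        ds = sample_negatives(positives, proteins, reactions, a,
                              {"train": 3, "val": 1, "test": 1}, seed=7)
        for fold, ratio in (("train", 3), ("val", 1), ("test", 1)):
            rows = ds.by_fold(fold)
            npos = sum(1 for _, _, y in rows if y == 1)
            nneg = len(rows) - npos
            assert nneg == ratio * npos
        assert not (ds.positives() & ds.negatives())

    def test_seed_reproducible(self, setup):
        a, proteins, reactions, positives = setup
        d1 = sample_negatives(positives, proteins, reactions, a,
                              {"train": 3, "val": 1, "test": 1}, seed=7)
        d2 = sample_negatives(positives, proteins, reactions, a,
                              {"train": 3, "val": 1, "test": 1}, seed=7)
        assert d1.pairs == d2.pairs
        d3 = sample_negatives(positives, proteins, reactions, a,
                              {"train": 3, "val": 1, "test": 1}, seed=8)
        assert d1.negatives() != d3.negatives()

    def test_insufficient_unobserved_pairs_error(self, setup):
        a, proteins, reactions, _ = setup
        complete = [(p, r) for p in proteins for r in reactions]
        with pytest.raises(ValueError, match="unobserved"):
            sample_negatives(complete, proteins, reactions, a,
                             {"train": 3, "val": 1, "test": 1}, seed=0)

    def test_nonpositive_ratio_rejected(self, setup):
        a, proteins, reactions, positives = setup
        with pytest.raises(ValueError, match="positive integer"):
            sample_negatives(positives, proteins, reactions, a,
                             {"train": 0, "val": 1, "test": 1}, seed=0)


class TestMisassignmentBound:
    def test_reference_sparsity_case(self):
        # 0.03% observed density, >=10% assumed coverage: bound 0.3%, under 3%
        assert misassignment_bound(0.0003, 0.10) == pytest.approx(0.003)
        assert misassignment_bound(0.0003, 0.10) < 0.03

    def test_full_coverage_returns_density(self):
        assert misassignment_bound(0.01, 1.0) == pytest.approx(0.01)

    def test_low_coverage_scales_inversely(self):
        assert misassignment_bound(0.0003, 0.01) == pytest.approx(0.03)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            misassignment_bound(0.2, 0.1)
        with pytest.raises(ValueError):
            misassignment_bound(0.0, 0.5)
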