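import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scipso.filters import (
    GenePool,
    GeneSubset,
    build_first_level_pool,
    build_third_level_pool,
    generate_candidate_subsets,
    iic_scores,
    score_genes,
    screen_and_rank_subsets,
)


def two_class_gene(mu1, sigma1, mu2, sigma2, n=40, seed=0):
    """Column vector with exact per-class sample mean/sd by construction."""
    rng = np.random.default_rng(seed)
    half = n // 2

    def block(mu, sigma):
        z = rng.normal(size=half)
        z = (z - z.mean()) / z.std(ddof=1)
        return mu + sigma * z

    x = np.concatenate([block(mu1, sigma1), block(mu2, sigma2)])[:, None]
    labels = np.repeat([1, 2], half)
    return x, labels


class TestIICStatistic:
    def test_identical_class_distributions_score_zero(self):
        x, labels = two_class_gene(1.0, 2.0, 1.0, 2.0)
        assert iic_scores(x, labels)[0] == pytest.approx(0.0, abs=1e-12)

    def test_unit_separation_hand_value(self):
        # mu 0 vs 1, sigma 1 each: each ordered class pair contributes
        # 0.5 * 1/2 + 0.5 * ln(1) = 0.25, and both orderings count
        x, labels = two_class_gene(0.0, 1.0, 1.0, 1.0)
        assert iic_scores(x, labels)[0] == pytest.approx(0.5, abs=1e-10)

    def test_monotone_in_mean_separation(self):
        scores = []
        for mu2 in [0.5, 1.0, 2.0, 4.0]:
            x, labels = two_class_gene(0.0, 1.0, mu2, 1.0)
            scores.append(iic_scores(x, labels)[0])
        assert np.all(np.diff(scores) > 0)

    def test_three_class_double_sum_counts_ordered_pairs(self):
        # classes at means 0, 1, 2 with sd 1: pairs (1,2),(1,3),(2,3)
        # contribute 0.25, 0.5, 0.25 each, twice (both orderings)
        rng = np.random.default_rng(1)

        def block(mu):
            z = rng.normal(size=10)
            z = (z - z.mean()) / z.std(ddof=1)
            return mu + z

        x = np.concatenate([block(0.0), block(1.0), block(2.0)])[:, None]
        labels = np.repeat([1, 2, 3], 10)
        assert iic_scores(x, labels)[0] == pytest.approx(2.0, abs=1e-10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        seed=st.integers(0, 1000),
    )
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(24, 1)) + np.repeat([0, 1.5], 12)[:, None]
        labels = np.repeat([1, 2], 12)
        d0 = iic_scores(x, labels)[0]
        d1 = iic_scores(a * x + b, labels)[0]
        assert d1 == pytest.approx(d0, rel=1e-8)

    def test_variance_floor_keeps_score_finite(self):
        x = np.repeat([0.0, 1.0], 5)[:, None]  # constant within class
        labels = np.repeat([1, 2], 5)
        with pytest.warns(UserWarning, match="floor"):
            d = iic_scores(x, labels)
        assert np.isfinite(d[0]) and d[0] > 0


class TestFirstLevelPool:
    def test_planted_genes_dominate_pool(self, planted_dataset):
        ds, truth = planted_dataset
        pool = build_first_level_pool(ds.values, ds.labels, n_top=50)
        assert set(truth.tolist()) <= set(pool.gene_indices.tolist())

    def test_pool_ordered_by_score(self, planted_dataset):
        ds, _ = planted_dataset
        pool = build_first_level_pool(ds.values, ds.labels, n_top=30)
        assert np.all(np.diff(pool.scores) <= 0)

    def test_full_pool_is_identity(self, tiny_dataset):
        pool = build_first_level_pool(tiny_dataset.values, tiny_dataset.labels, n_top=3)
        assert sorted(pool.gene_indices.tolist()) == [0, 1, 2]

    def test_constant_data_tie_breaks_to_low_indices(self):
        X = np.ones((6, 5))
        labels = np.repeat([1, 2], 3)
        with pytest.warns(UserWarning):
            pool = build_first_level_pool(X, labels, n_top=3)
        assert pool.gene_indices.tolist() == [0, 1, 2]

    @pytest.mark.parametrize("n_top", [0, 6])
    def test_out_of_range_pool_size_rejected(self, tiny_dataset, n_top):
        with pytest.raises(ValueError):
            build_first_level_pool(tiny_dataset.values, tiny_dataset.labels, n_top=n_top)


class TestCandidateSubsets:
    def test_sizes_and_count(self):
        pool = GenePool(level=1, gene_indices=np.arange(50))
        subs = generate_candidate_subsets(pool, 100, size_range=(5, 15), seed=3)
        assert len(subs) == 100
        sizes = {len(s.gene_indices) for s in subs}
        assert sizes <= set(range(5, 16))
        for s in subs:
            assert len(set(s.gene_indices)) == len(s.gene_indices)

    def test_singleton_boundary(self):
        pool = GenePool(level=1, gene_indices=np.arange(10))
        subs = generate_candidate_subsets(pool, 5, size_range=(1, 1), seed=0)
        assert all(len(s.gene_indices) == 1 for s in subs)

    def test_deterministic_given_seed(self):
        pool = GenePool(level=1, gene_indices=np.arange(30))
        a = generate_candidate_subsets(pool, 20, seed=8)
        b = generate_candidate_subsets(pool, 20, seed=8)
        assert [s.gene_indices for s in a] == [s.gene_indices for s in b]


class TestScreening:
    def test_zero_threshold_keeps_all(self, separable_dataset):
        pool = GenePool(level=1, gene_indices=np.arange(6))
        subs = generate_candidate_subsets(pool, 10, size_range=(2, 4), seed=1)
        ranked = screen_and_rank_subsets(
            subs, separable_dataset.values, separable_dataset.labels, theta_ac=0.0
        )
        assert len(ranked) == 10
        assert [s.rank for s in ranked] == list(range(1, 11))
        accs = [s.cv_accuracy for s in ranked]
        assert accs == sorted(accs, reverse=True)

    def test_out_of_range_threshold_rejected(self, separable_dataset):
        pool = GenePool(level=1, gene_indices=np.arange(6))
        subs = generate_candidate_subsets(pool, 3, size_range=(2, 3), seed=1)
        with pytest.raises(ValueError):
            screen_and_rank_subsets(
                subs, separable_dataset.values, separable_dataset.labels, theta_ac=1.01
            )

    def test_zero_survivors_fails_loudly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 6))  # pure noise cannot hit accuracy 1.0
        labels = np.repeat([1, 2], 10)
        pool = GenePool(level=1, gene_indices=np.arange(6))
        subs = generate_candidate_subsets(pool, 5, size_range=(2, 3), seed=2)
        with pytest.raises(ValueError, match="lower the threshold"):
            screen_and_rank_subsets(subs, X, labels, theta_ac=1.0)

    def test_accuracy_tie_prefers_smaller_subset(self, separable_dataset):
        subs = [
            GeneSubset(gene_indices=(0, 1, 2, 3), draw_order=0),
            GeneSubset(gene_indices=(0, 1), draw_order=1),
        ]
        ranked = screen_and_rank_subsets(
            subs, separable_dataset.values, separable_dataset.labels, theta_ac=0.9
        )
        assert ranked[0].gene_indices == (0, 1)


class TestGeneScoring:
    def test_hand_example_reversed_rank_weights(self):
        # gene 0 in subsets ranked 1 and 2; gene 1 in subsets ranked 3 and 4
        ranked = [
            GeneSubset(gene_indices=(0, 2), cv_accuracy=0.9, rank=1),
            GeneSubset(gene_indices=(0, 3), cv_accuracy=0.8, rank=2),
            GeneSubset(gene_indices=(1, 2), cv_accuracy=0.7, rank=3),
            GeneSubset(gene_indices=(1, 3), cv_accuracy=0.6, rank=4),
        ]
        scores = score_genes(ranked, n_genes=5)
        # raw: g0 = 4+3 = 7, g1 = 2+1 = 3, g2 = 4+2 = 6, g3 = 3+1 = 4, g4 = 0
        assert scores[0] == pytest.approx(1.0)
        assert scores[4] == 0.0
        # min-max over member genes: the weakest member lands on 0
        assert scores[0] > scores[2] > scores[3] > scores[1]
        raw = np.array([7, 3, 6, 4], dtype=float)
        np.testing.assert_allclose(scores[:4], (raw - 3) / 4)

    def test_single_subset_members_score_one(self):
        ranked = [GeneSubset(gene_indices=(0, 1), cv_accuracy=1.0, rank=1)]
        scores = score_genes(ranked, n_genes=3)
        assert scores[0] == scores[1] == 1.0
        assert scores[2] == 0.0

    def test_degenerate_min_max_maps_to_one(self):
        ranked = [
            GeneSubset(gene_indices=(0, 1), cv_accuracy=0.9, rank=1),
            GeneSubset(gene_indices=(0, 1), cv_accuracy=0.8, rank=2),
        ]
        scores = score_genes(ranked, n_genes=2)
        np.testing.assert_array_equal(scores, [1.0, 1.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 500))
    def test_extra_membership_never_decreases_score(self, seed):
        rng = np.random.default_rng(seed)
        n_sub = int(rng.integers(2, 8))
        subsets = []
        for r in range(1, n_sub + 1):
            genes = tuple(int(g) for g in rng.choice(10, size=3, replace=False))
            subsets.append(GeneSubset(gene_indices=genes, cv_accuracy=1 - r / 10, rank=r))
        raw_before = np.zeros(10)
        for s in subsets:
            raw_before[list(s.gene_indices)] += n_sub - s.rank + 1
        # add gene 0 to the last subset if absent
        target = subsets[-1]
        if 0 not in target.gene_indices:
            target.gene_indices = target.gene_indices + (0,)
        raw_after = np.zeros(10)
        for s in subsets:
            raw_after[list(s.gene_indices)] += n_sub - s.rank + 1
        assert raw_after[0] >= raw_before[0]

    def test_gapped_ranks_rejected(self):
        ranked = [GeneSubset(gene_indices=(0,), cv_accuracy=0.9, rank=2)]
        with pytest.raises(ValueError, match="rank"):
            score_genes(ranked, n_genes=2)


class TestThirdLevelPool:
    def test_requested_size_honoured(self):
        scores = np.linspace(1, 0.01, 100)
        pool = build_third_level_pool(scores, pool_size=40)
        assert len(pool) == 40
        assert pool.level == 3

    def test_identity_on_scored_set(self):
        scores = np.array([0.5, 0.0, 1.0, 0.25])
        pool = build_third_level_pool(scores, pool_size=3)
        assert pool.gene_indices.tolist() == [2, 0, 3]

    def test_short_pool_warns_and_shrinks(self):
        scores = np.array([0.9, 0.0, 0.0, 0.4])
        with pytest.warns(UserWarning, match="scored"):
            pool = build_third_level_pool(scores, pool_size=4)
        assert set(pool.gene_indices.tolist()) == {0, 3}

    def test_ties_break_by_iic_then_index(self):
        scores = np.array([0.5, 0.5, 0.5])
        iic = np.array([1.0, 3.0, 3.0])
        pool = build_third_level_pool(scores, pool_size=3, iic=iic)
        assert pool.gene_indices.tolist() == [1, 2, 0]


class TestPoolNesting:
    def test_cascade_nesting_invariant(self, planted_dataset):
        ds, _ = planted_dataset
        pool1 = build_first_level_pool(ds.values, ds.labels, n_top=60)
        subs = generate_candidate_subsets(pool1, 200, size_range=(3, 8), seed=5)
        ranked = screen_and_rank_subsets(subs, ds.values, ds.labels, theta_ac=0.5, seed=5)
        scores = score_genes(ranked, n_genes=ds.n_genes)
        pool3 = build_third_level_pool(scores, pool_size=20)
        level2_genes = set().union(*(s.gene_indices for s in ranked))
        assert set(pool3.gene_indices.tolist()) <= level2_genes
        assert level2_genes <= set(pool1.gene_indices.tolist())
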