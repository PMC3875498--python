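"""The clustering engine: sampling, representatives, agglomeration, labeling."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from catser.cluster import (
    Cluster,
    MergeTree,
    OutlierStrategy,
    RepCountConfig,
    STRATEGY_PRESETS,
    _distance_row,
    _pair_distance,
    agglomerate,
    cluster_distance,
    draw_sample,
    estimate_sample_size,
    find_medoid,
    fisher_yates,
    intra_distance,
    lof_correction,
    num_representatives,
    partition,
    reassign_or_label,
    run_catser,
    select_representatives,
)
from catser.config import RunConfig
from catser.similarity import compute_similarity_matrix
from catser.synthetic import default_bundle_specs, generate_bundles
from catser.tracts import Tract, TractDataset


def point_dataset(points: np.ndarray) -> TractDataset:
    eps = np.array([5e-7, 0, 0])
    return TractDataset([Tract(np.vstack([p - eps, p + eps]), i)
                         for i, p in enumerate(np.atleast_2d(points))])


def dense_from_points(points: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.atleast_2d(points)))


class TestSampleSize:
    def test_limit_cases(self):
        # delta -> 1 kills the log terms; fraction -> 0 kills the first
        assert estimate_sample_size(10000, 100, 1e-9, 1 - 1e-12) == 1
        # dominance: the bound is never below f * N
        for f in (0.1, 0.5, 0.9):
            assert estimate_sample_size(5000, 50, f, 0.01) >= f * 5000

    def test_cure_closed_form_value(self):
        # direct evaluation of the closed-form bound
        assert estimate_sample_size(10000, 100, 0.1, 0.001) == 3055

    def test_clamped_to_total(self):
        assert estimate_sample_size(100, 10, 0.99, 1e-6) == 100

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            estimate_sample_size(100, 200, 0.1, 0.01)
        with pytest.raises(ValueError):
            estimate_sample_size(100, 10, 0.0, 0.01)


class TestSampling:
    def test_full_sample_is_permutation(self):
        sample, rem = draw_sample(20, 20, seed=7)
        assert sorted(sample) == list(range(20))
        assert len(rem) == 0

    def test_deterministic(self):
        s1, r1 = draw_sample(100, 40, seed=3)
        s2, r2 = draw_sample(100, 40, seed=3)
        assert np.array_equal(s1, s2) and np.array_equal(r1, r2)

    def test_disjoint_union(self):
        s, r = draw_sample(57, 23, seed=1)
        assert sorted(np.concatenate([s, r])) == list(range(57))

    def test_uniform_inclusion_frequency(self):
        # Monte-Carlo: each id's inclusion frequency for size N/2 near 0.5
        n, size, trials = 10, 5, 10000
        counts = np.zeros(n)
        for seed in range(trials):
            s, _ = draw_sample(n, size, seed=seed)
            counts[s] += 1
        freq = counts / trials
        sigma = np.sqrt(0.5 * 0.5 / trials)
        assert np.all(np.abs(freq - 0.5) < 3 * sigma + 0.01)

    def test_fisher_yates_covers_permutations(self):
        # with n=3 all 6 permutations should appear
        seen = {tuple(fisher_yates(3, np.random.default_rng(s))) for s in range(200)}
        assert len(seen) == 6

    def test_size_out_of_range(self):
        with pytest.raises(ValueError):
            draw_sample(10, 0, seed=0)
        with pytest.raises(ValueError):
            draw_sample(10, 11, seed=0)


class TestPartition:
    @pytest.mark.parametrize("n,k,sizes", [(10, 3, {4, 3}), (9, 3, {3})])
    def test_balanced_sizes(self, n, k, sizes):
        parts = partition(np.arange(n), k, seed=0)
        assert {len(p) for p in parts} == sizes

    def test_union_and_disjoint(self, rng):
        ids = rng.choice(1000, 97, replace=False)
        parts = partition(ids, 5, seed=2)
        merged = sorted(np.concatenate(parts))
        assert merged == sorted(ids)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            partition(np.arange(5), 6, seed=0)


class TestRepCount:
    def test_study_configuration(self):
        cfg = RepCountConfig(ratio=40 / 120, n_t=120, m_max=40)
        assert num_representatives(120, cfg) == 40
        assert num_representatives(300, cfg) == 40

    def test_small_cluster_floor(self):
        cfg = RepCountConfig(ratio=1 / 3, n_t=120, m_max=40)
        assert num_representatives(3, cfg) == 1
        assert num_representatives(1, cfg) == 1

    def test_monotone_and_bounded(self):
        cfg = RepCountConfig(ratio=40 / 120, n_t=120, m_max=40)
        prev = 0
        for n in range(1, 400):
            m = num_representatives(n, cfg)
            assert 1 <= m <= n
            assert m >= prev
            prev = m


class TestMedoidAndReps:
    def test_singleton(self):
        assert find_medoid([3], np.zeros((5, 5))) == 3

    def test_collinear_middle(self):
        dense = dense_from_points(np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]))
        assert find_medoid([0, 1, 2], dense) == 1

    def test_matches_brute_force(self, rng):
        pts = rng.random((20, 3)) * 10
        dense = dense_from_points(pts)
        members = list(range(20))
        ref = min(members, key=lambda i: (dense[i, members].mean(), i))
        assert find_medoid(members, dense) == ref

    def test_collinear_reps_are_endpoints(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        dense = dense_from_points(pts)
        c = Cluster(0, [0, 1, 2, 3, 4], 2, [])
        cfg = RepCountConfig(ratio=2 / 5, n_t=100, m_max=40)
        reps = select_representatives(c, dense, np.ones(5), cfg)
        assert set(reps) == {0, 4}

    def test_high_lof_member_not_selected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        dense = dense_from_points(pts)
        c = Cluster(0, [0, 1, 2, 3, 4], 2, [])
        cfg = RepCountConfig(ratio=2 / 5, n_t=100, m_max=40)
        lofs = np.ones(5)
        lofs[4] = 25.0  # strong attraction penalty on the far endpoint
        reps = select_representatives(c, dense, lofs, cfg)
        assert 4 not in reps


class TestLofAdjustments:
    def test_neutral_when_not_outlying(self):
        assert lof_correction(1.0, 1.0) == 1.0
        assert lof_correction(0.5, 0.9) == 1.0

    def test_increases_when_outlying(self):
        assert lof_correction(0.9, 5.0) > 1.0
        assert lof_correction(3.0, 3.0) > lof_correction(2.0, 3.0)

    def test_symmetric(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.5, 10, 2)
            assert lof_correction(a, b) == pytest.approx(lof_correction(b, a))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            lof_correction(0.0, 1.0)

    def test_intra_distance_attraction(self):
        dense = np.array([[0.0, 4.0], [4.0, 0.0]])
        assert intra_distance(0, 1, dense, np.array([1.0, 1.0])) == 4.0
        adjusted = intra_distance(0, 1, dense, np.array([1.0, 5.0]))
        assert adjusted < 4.0

    def test_intra_monotone_in_lof(self):
        dense = np.array([[0.0, 4.0], [4.0, 0.0]])
        prev = np.inf
        for lof in np.linspace(1.0, 10.0, 10):
            d = intra_distance(0, 1, dense, np.array([1.0, lof]))
            assert d <= prev
            prev = d

    def test_cluster_distance_repulsion_and_neutral_weight(self):
        dense = dense_from_points(np.array([[0.0, 0, 0], [5, 0, 0]]))
        a = Cluster(0, [0], 0, [0])
        b = Cluster(1, [1], 1, [1])
        assert cluster_distance(a, b, dense, np.ones(2)) == pytest.approx(5.0)
        elevated = cluster_distance(a, b, dense, np.array([1.0, 4.0]))
        assert elevated > 5.0
        assert cluster_distance(a, b, dense, np.ones(2), guidance_weight=1.0) == \
            pytest.approx(cluster_distance(a, b, dense, np.ones(2)))


class TestAgglomerate:
    def _singletons(self, n):
        return [Cluster(i, [i], i, [i]) for i in range(n)]

    def test_no_merges_at_target(self):
        dense = dense_from_points(np.random.default_rng(0).random((5, 3)))
        tree = MergeTree(leaf_ids=list(range(5)))
        cl, outs = agglomerate(self._singletons(5), 5, None, dense, np.ones(5),
                               tree, RepCountConfig())
        assert len(cl) == 5 and not outs and not tree.merges

    def test_recovers_separated_groups(self, rng):
        groups = [rng.normal(c, 0.3, (10, 3)) for c in ([0, 0, 0], [10, 0, 0], [0, 10, 0])]
        pts = np.vstack(groups)
        dense = dense_from_points(pts)
        tree = MergeTree(leaf_ids=list(range(30)))
        cl, outs = agglomerate(self._singletons(30), 3, None, dense, np.ones(30),
                               tree, RepCountConfig(ratio=1.0, n_t=10 ** 9, m_max=10 ** 9))
        assert sorted(sorted(c.member_ids) for c in cl) == [
            list(range(0, 10)), list(range(10, 20)), list(range(20, 30))]

    def test_isolated_points_removed(self, rng):
        groups = [rng.normal(c, 0.3, (12, 3)) for c in ([0, 0, 0], [10, 0, 0], [0, 10, 0])]
        pts = np.vstack(groups + [np.array([[50.0, 50, 50], [-40, 7, 60]])])
        dense = dense_from_points(pts)
        lofs = np.ones(38)
        lofs[36:] = 10.0
        tree = MergeTree(leaf_ids=list(range(38)))
        strat = STRATEGY_PRESETS["moderate"]
        cl, outs = agglomerate(self._singletons(38), 3, (strat.t2, strat.s2),
                               dense, lofs, tree, RepCountConfig())
        assert {36, 37} <= set(outs)

    def test_distance_row_matches_pairwise(self, rng):
        pts = rng.random((30, 3)) * 10
        dense = dense_from_points(pts)
        rlof = np.sqrt(np.maximum(rng.uniform(0.5, 4.0, 30), 1.0))
        clusters = [Cluster(i, m, m[0], m) for i, m in enumerate(
            [[0, 1, 2], [3, 4], [5], [6, 7, 8, 9], [10, 11]])]
        row = _distance_row([12, 13, 14], clusters, dense, rlof)
        ref = [_pair_distance([12, 13, 14], c.representative_ids, dense, rlof)
               for c in clusters]
        assert np.allclose(row, ref, rtol=1e-12)

    def test_merge_tree_replay(self, rng):
        pts = rng.random((25, 3)) * 20
        dense = dense_from_points(pts)
        tree = MergeTree(leaf_ids=list(range(25)))
        cl, outs = agglomerate(self._singletons(25), 4, (80.0, 1), dense,
                               np.ones(25), tree, RepCountConfig())
        replayed = tree.replay()
        assert sorted(map(sorted, replayed.values())) == \
            sorted(sorted(c.member_ids) for c in cl)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            agglomerate(self._singletons(3), 0, None, np.zeros((3, 3)),
                        np.ones(3), MergeTree(leaf_ids=[0, 1, 2]), RepCountConfig())


class TestReassign:
    def test_zero_distance_assigned(self):
        assert reassign_or_label({7: np.array([0.0, 2.0])}, {7: 1.0}, 2.0) == 7

    def test_far_tract_is_outlier(self):
        assert reassign_or_label({7: np.array([50.0])}, {7: 1.0}, 2.0) == -1

    def test_assignment_set_grows_with_gamma(self):
        dists = {1: np.array([3.0]), 2: np.array([8.0])}
        sigmas = {1: 1.0, 2: 1.0}
        assigned = [reassign_or_label(dists, sigmas, g) for g in (0.5, 3.5, 10.0)]
        assert assigned == [-1, 1, 1]

    def test_rejects_bad_gamma(self):
        with pytest.raises(ValueError):
            reassign_or_label({1: np.array([1.0])}, {1: 1.0}, 0.0)


class TestRunCatser:
    def test_single_linkage_reduction(self, rng):
        """Full sample, one partition, all-member representatives, unit LOFs,
        no elimination: the dendrogram cut equals textbook single linkage."""
        pts = rng.random((60, 3)) * 40
        ds = point_dataset(pts)
        cfg = RunConfig(
            measure="tcd", sample_size=60, n_partitions=1, k=1,
            rep=RepCountConfig(ratio=1.0, n_t=10 ** 9, m_max=10 ** 9),
            strategy="none", lof_neutral=True, target_clusters=6,
            precluster_reduction=1.0, seed=0)
        res = run_catser(ds, cfg)
        got = sorted(sorted(c.member_ids) for c in res.clusters)
        Z = linkage(pdist(pts), method="single")
        ref_labels = fcluster(Z, t=6, criterion="maxclust")
        ref = sorted(sorted(np.flatnonzero(ref_labels == k).tolist())
                     for k in set(ref_labels))
        assert got == ref

    def test_labels_partition_dataset(self, rng):
        ds, truth = generate_bundles(default_bundle_specs(3, 30), rng)
        cfg = RunConfig(measure="tcd", sample_size=60, n_partitions=2,
                        target_clusters=3, k=5, strategy="moderate", seed=1)
        res = run_catser(ds, cfg)
        n = len(ds)
        assigned = sum(len(c.member_ids) for c in res.clusters)
        assert assigned + len(res.outlier_ids) == n
        for c in res.clusters:
            assert set(np.flatnonzero(res.labels == c.id)) == set(c.member_ids)

    def test_seed_reproducibility(self, rng):
        ds, _ = generate_bundles(default_bundle_specs(3, 30), rng)
        cfg = RunConfig(measure="tcd", sample_size=60, n_partitions=2,
                        target_clusters=3, k=5, strategy="moderate", seed=9)
        r1, r2 = run_catser(ds, cfg), run_catser(ds, cfg)
        assert np.array_equal(r1.labels, r2.labels)
        assert [c.member_ids for c in r1.clusters] == [c.member_ids for c in r2.clusters]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            run_catser(TractDataset([]), RunConfig())
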