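import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from pentalayout.clustering import (
    ClusterSweepConfig,
    ConsensusMatrix,
    Partition,
    consensus_cooccurrence,
    pca_whiten,
    quantum_cluster,
    run_sweep,
    spectral_cocluster,
    ward_cluster,
)


def brute_force_ward_heights(points):
    """Greedy Ward agglomeration by exhaustive pair enumeration.

    Tracks cluster members; the merge cost for clusters A, B is the
    increase in within-cluster sum of squares,
    ``|A||B| / (|A|+|B|) * ||centroid_A - centroid_B||^2``; the reported
    height is ``sqrt(2 * cost)`` (the Euclidean distance for singletons).
    """
    clusters = [[i] for i in range(len(points))]
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                ca = points[clusters[a]].mean(axis=0)
                cb = points[clusters[b]].mean(axis=0)
                na, nb = len(clusters[a]), len(clusters[b])
                cost = na * nb / (na + nb) * float(((ca - cb) ** 2).sum())
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        cost, a, b = best
        heights.append(np.sqrt(2.0 * cost))
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return np.array(heights)


def two_blob_embedding(seed=1, n_per_blob=30, separation=20.0, sd=1.0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0.0, 0.0], sd, size=(n_per_blob, 2))
    b = rng.normal([separation * sd, 0.0], sd, size=(n_per_blob, 2))
    pts = np.vstack([a, b])
    labels = np.array([0] * n_per_blob + [1] * n_per_blob)
    return pts, labels


class TestWardCluster:
    def test_separated_pairs_merge_first(self):
        data = np.array([[0.0], [0.1], [10.0], [10.1]])
        dend = ward_cluster(data, ["a", "b", "c", "d"])
        first, second = dend.merges[0], dend.merges[1]
        merged = {frozenset(first[:2]), frozenset(second[:2])}
        assert merged == {frozenset({0, 1}), frozenset({2, 3})}

    def test_two_items_merge_at_euclidean_distance(self):
        data = np.array([[0.0, 0.0], [3.0, 4.0]])
        dend = ward_cluster(data, ["a", "b"])
        assert dend.merges[0][2] == pytest.approx(5.0)

    def test_heights_match_brute_force_on_random_points(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(5, 3))
        dend = ward_cluster(data, list("abcde"))
        assert np.allclose(dend.heights, brute_force_ward_heights(data))

    @given(st.integers(0, 10_000), st.integers(3, 7))
    @settings(max_examples=60, deadline=None)
    def test_brute_force_property(self, seed, n):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(n, 2))
        dend = ward_cluster(data, [str(i) for i in range(n)])
        assert np.allclose(dend.heights, brute_force_ward_heights(data))

    def test_heights_nondecreasing(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(12, 4))
        dend = ward_cluster(data, [str(i) for i in range(12)])
        assert (np.diff(dend.heights) >= -1e-12).all()

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="finite"):
            ward_cluster(np.array([[np.nan], [1.0]]), ["a", "b"])

    def test_columns_axis(self):
        data = np.array([[0.0, 0.0, 9.0], [0.1, 0.0, 9.0]])
        dend = ward_cluster(data, ["c1", "c2", "c3"], axis="columns")
        assert frozenset(dend.merges[0][:2]) == frozenset({0, 1})

    def test_newick_round_trip_labels(self):
        data = np.array([[0.0], [1.0], [5.0]])
        nwk = ward_cluster(data, ["x", "y", "z"]).to_newick()
        assert nwk.endswith(";")
        for label in ("x", "y", "z"):
            assert label in nwk


class TestPcaWhiten:
    def test_white_data_stays_white(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(500, 2))
        emb, _ = pca_whiten(data, n_components=2)
        cov = np.cov(emb, rowvar=False, ddof=0)
        assert np.allclose(cov, np.eye(2), atol=1e-8)

    def test_rank_deficient_truncates_with_warning(self):
        base = np.outer(np.arange(10, dtype=float), [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="rank"):
            emb, explained = pca_whiten(base, n_components=5)
        assert emb.shape[1] == 1
        assert explained[0] == pytest.approx(1.0)

    def test_fixture_explained_variance(self):
        # low regional noise leaves the planted latent factors and
        # enrichments carrying most of the variance
        from pentalayout.synthetic import default_regional_truth, simulate_regional

        truth = default_regional_truth(subject_sd=0.1, regional_sd=0.25)
        mats, _ = simulate_regional(truth, seed=1)
        emb, explained = pca_whiten(mats[0].values.T, n_components=5)
        assert explained.sum() > 0.8

    def test_needs_multiple_items(self):
        with pytest.raises(ValueError):
            pca_whiten(np.ones((1, 3)))


class TestQuantumCluster:
    def test_single_point_single_cluster(self):
        p = quantum_cluster(np.array([[1.0, 2.0]]), sigma=1.0)
        assert p.n_clusters() == 1

    def test_huge_sigma_single_cluster(self):
        pts, _ = two_blob_embedding(seed=3)
        p = quantum_cluster(pts, sigma=1000.0)
        assert p.n_clusters() == 1

    def test_two_blobs_recovered(self):
        pts, labels = two_blob_embedding(seed=1)
        p = quantum_cluster(pts, sigma=1.5)
        found = p.labels_for([str(i) for i in range(len(pts))])
        assert adjusted_rand_score(labels, found) == 1.0

    def test_translation_invariance(self):
        pts, _ = two_blob_embedding(seed=4, n_per_blob=15)
        a = quantum_cluster(pts, sigma=1.0)
        b = quantum_cluster(pts + 1234.5, sigma=1.0)
        items = [str(i) for i in range(len(pts))]
        assert adjusted_rand_score(a.labels_for(items), b.labels_for(items)) == 1.0

    def test_scaling_equivariance(self):
        pts, _ = two_blob_embedding(seed=5, n_per_blob=15)
        a = quantum_cluster(pts, sigma=1.0)
        b = quantum_cluster(pts * 7.0, sigma=7.0)
        items = [str(i) for i in range(len(pts))]
        assert adjusted_rand_score(a.labels_for(items), b.labels_for(items)) == 1.0

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError, match="sigma"):
            quantum_cluster(np.zeros((3, 2)), sigma=0.0)


class TestSpectralCocluster:
    def test_block_diagonal_two_blocks(self):
        X = np.zeros((6, 8))
        X[:3, :4] = 5.0
        X[3:, 4:] = 5.0
        rows, cols = spectral_cocluster(
            X, 2, [f"r{i}" for i in range(6)], [f"c{j}" for j in range(8)]
        )
        row_labels = rows.labels_for([f"r{i}" for i in range(6)])
        col_labels = cols.labels_for([f"c{j}" for j in range(8)])
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], row_labels) == 1.0
        assert adjusted_rand_score([0, 0, 0, 0, 1, 1, 1, 1], col_labels) == 1.0

    def test_constant_matrix_degenerate_warning(self):
        X = np.ones((4, 4))
        with pytest.warns(UserWarning, match="degenerate"):
            rows, cols = spectral_cocluster(
                X, 2, list("abcd"), list("wxyz")
            )
        assert set(rows.assignment) == set("abcd")

    def test_planted_three_biclusters(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 0.05, size=(9, 12))
        truth_rows = [0] * 3 + [1] * 3 + [2] * 3
        truth_cols = [0] * 4 + [1] * 4 + [2] * 4
        for i, r in enumerate(truth_rows):
            for j, c in enumerate(truth_cols):
                if r == c:
                    X[i, j] += 5.0
        rows, _ = spectral_cocluster(
            X, 3, [f"r{i}" for i in range(9)], [f"c{j}" for j in range(12)]
        )
        found = rows.labels_for([f"r{i}" for i in range(9)])
        assert adjusted_rand_score(truth_rows, found) == 1.0

    def test_k_bounds(self):
        X = np.ones((3, 5))
        with pytest.raises(ValueError, match="exceeds"):
            spectral_cocluster(X, 4, list("abc"), list("vwxyz"))
        with pytest.raises(ValueError, match=">= 2"):
            spectral_cocluster(X, 1, list("abc"), list("vwxyz"))


class TestConsensus:
    def _partition(self, assignment, **kwargs):
        return Partition(assignment, **kwargs)

    def test_identical_partitions(self):
        p = self._partition({"a": 0, "b": 0, "c": 1})
        cm = consensus_cooccurrence([p, p, p])
        i = {item: k for k, item in enumerate(cm.items)}
        assert cm.values[i["a"], i["b"]] == 1.0
        assert cm.values[i["a"], i["c"]] == 0.0
        assert cm.n_runs == 3

    def test_half_cooccurrence(self):
        p1 = self._partition({"a": 0, "b": 0})
        p2 = self._partition({"a": 0, "b": 1})
        cm = consensus_cooccurrence([p1, p2])
        i = {item: k for k, item in enumerate(cm.items)}
        assert cm.values[i["a"], i["b"]] == 0.5

    def test_item_mismatch_names_difference(self):
        p1 = self._partition({"a": 0, "b": 0})
        p2 = self._partition({"a": 0, "z": 0})
        with pytest.raises(ValueError, match="z"):
            consensus_cooccurrence([p1, p2])

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        parts = [
            self._partition({f"i{k}": int(rng.integers(3)) for k in range(10)})
            for _ in range(7)
        ]
        cm = consensus_cooccurrence(parts)
        assert np.allclose(cm.values, cm.values.T)
        assert np.allclose(np.diag(cm.values), 1.0)
        assert cm.values.min() >= 0 and cm.values.max() <= 1

    def test_sigma_sweep_on_blobs_recovers_bipartition(self):
        pts, labels = two_blob_embedding(seed=1)
        items = [str(i) for i in range(len(pts))]
        parts = [
            quantum_cluster(pts, sigma=s, labels=items)
            for s in (0.5, 1.0, 2.0, 3.0, 5.0)
        ]
        cm = consensus_cooccurrence(parts)
        blocks = cm.blocks(threshold=0.5)
        found = [blocks[i] for i in items]
        assert adjusted_rand_score(labels, found) == 1.0


class TestRunSweep:
    def test_partition_counting_minimal_grids(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 2, size=(8, 5))
        cfg = ClusterSweepConfig(sigma_grid=(1.0,), k_grid=(2,),
                                 transforms=("log2",), n_components=3)
        consensus, parts = run_sweep(
            {"log2": (X, [f"r{i}" for i in range(8)], [f"c{j}" for j in range(5)])},
            cfg,
        )
        assert len(parts) == 2
        assert consensus.n_runs == 2

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(1, 2, size=(10, 6))
        args = {"log2": (X, [f"r{i}" for i in range(10)], [f"c{j}" for j in range(6)])}
        cfg = ClusterSweepConfig(sigma_grid=(0.5, 1.0), k_grid=(2, 3),
                                 transforms=("log2",), n_components=3)
        a, _ = run_sweep(args, cfg, seed=7)
        b, _ = run_sweep(args, cfg, seed=7)
        assert (a.values == b.values).all()

    def test_config_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            ClusterSweepConfig(sigma_grid=())
        with pytest.raises(ValueError, match="positive"):
            ClusterSweepConfig(sigma_grid=(0.0,))
        with pytest.raises(ValueError, match=">= 2"):
            ClusterSweepConfig(k_grid=(1,))

    def test_planted_region_groups_recovered(self, panel):
        # three groups of regions with distinct gene signatures
        rng = np.random.default_rng(1)
        n_per, n_genes = 10, 19
        groups = []
        for g in range(3):
            center = rng.uniform(4, 10, n_genes)
            groups.append(center + rng.normal(0, 0.15, size=(n_per, n_genes)))
        X = np.vstack(groups)
        truth = [g for g in range(3) for _ in range(n_per)]
        rows = [f"r{i}" for i in range(3 * n_per)]
        cols = [f"g{j}" for j in range(n_genes)]
        lin = 2.0**X
        prop = lin / lin.sum(axis=1, keepdims=True) * 100
        # n_components matches the rank of the planted structure: with the
        # full 5, whitening inflates pure-noise directions and washes out
        # the group separation
        cfg = ClusterSweepConfig(
            sigma_grid=(0.2, 0.3, 0.4, 0.5), k_grid=(2, 3, 4),
            transforms=("log2", "proportional"), n_components=2,
        )
        consensus, _ = run_sweep(
            {"log2": (X, rows, cols), "proportional": (prop, rows, cols)}, cfg
        )
        blocks = consensus.blocks(threshold=0.5)
        found = [blocks[r] for r in rows]
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_missing_transform_raises(self):
        cfg = ClusterSweepConfig(transforms=("log2", "proportional"))
        with pytest.raises(KeyError, match="proportional"):
            run_sweep({"log2": (np.ones((3, 3)), list("abc"), list("xyz"))}, cfg)
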