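"""Standardisation, PCA, K-means/DBSCAN and silhouette model selection.

Silhouette and DBSCAN are checked against independent brute-force
implementations (O(n^2) loops / direct neighbourhood expansion) defined here.
"""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from drugrec import (
    ClusterConfig,
    DrugRecError,
    FittedClusterPipeline,
    assign_cluster,
    dbscan_cluster,
    fit_cluster_pipeline,
    fit_pca,
    kmeans_cluster,
    select_model,
    silhouette,
    standardize,
)
from drugrec.clustering import ClusteringModel

# ---------------------------------------------------------------- oracles


def brute_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """O(n^2) silhouette, written straight from the definition."""
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    values = []
    for i in range(n):
        own = labels[i]
        same = [j for j in range(n) if labels[j] == own and j != i]
        if not same:  # singleton convention
            values.append(0.0)
            continue
        a = np.mean([d[i, j] for j in same])
        b = min(
            np.mean([d[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != own
        )
        values.append((b - a) / max(a, b))
    return float(np.mean(values))


def brute_dbscan(x: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Direct neighbourhood-expansion DBSCAN (self counts as a neighbour)."""
    n = len(x)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps)) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        frontier = [i]
        labels[i] = cluster
        while frontier:
            j = frontier.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    frontier.append(k)
        cluster += 1
    return labels


def _partition(labels: np.ndarray) -> set:
    return {
        frozenset(np.flatnonzero(labels == c))
        for c in set(labels.tolist())
        if c != -1
    }


# ---------------------------------------------------------------- tests


class TestStandardize:
    def test_hand_computed_z_scores_population_sd(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        z, params = standardize(table)
        np.testing.assert_allclose(
            z["x"], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(3, 2, size=(50, 3)), columns=list("abc"))
        z1, _ = standardize(table)
        z2, _ = standardize(z1)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        z, _ = standardize(pd.DataFrame(rng.exponential(size=(40, 2))))
        assert np.abs(z.mean()).max() < 1e-10
        assert np.abs(z.std(ddof=0) - 1).max() < 1e-10

    def test_constant_column_named_in_error(self):
        table = pd.DataFrame({"ok": [1.0, 2.0], "flat": [5.0, 5.0]})
        with pytest.raises(DrugRecError, match="flat"):
            standardize(table)

    def test_params_invert_transform(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        z, params = standardize(table)
        np.testing.assert_allclose(
            params.inverse(z).to_numpy(), table.to_numpy(), atol=1e-12
        )


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(4)
        t = rng.normal(size=60)
        table = pd.DataFrame({"a": t, "b": 2 * t})
        z, _ = standardize(table)
        model, _ = fit_pca(z, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_rank_ratios_sum_to_one(self):
        rng = np.random.default_rng(5)
        z, _ = standardize(pd.DataFrame(rng.normal(size=(30, 4))))
        model, _ = fit_pca(z, 1.0)  # variance target 1.0 keeps everything
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_score_variances_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        z, _ = standardize(pd.DataFrame(rng.normal(size=(50, 6))))
        model, scores = fit_pca(z, 6)
        eig = np.sort(np.linalg.eigvalsh(np.cov(z.to_numpy().T)))[::-1]
        np.testing.assert_allclose(
            scores.var(axis=0, ddof=1), eig, atol=1e-10
        )

    def test_variance_target_picks_smallest_k(self):
        rng = np.random.default_rng(7)
        z, _ = standardize(pd.DataFrame(rng.normal(size=(40, 5))))
        model, _ = fit_pca(z, 0.5)
        ratios, k = model.explained_variance_ratio, model.k
        full, _ = fit_pca(z, 5)
        cum = np.cumsum(full.explained_variance_ratio)
        assert cum[k - 1] >= 0.5
        assert k == 1 or cum[k - 2] < 0.5

    def test_scores_invariant_to_feature_order(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        z1, _ = standardize(table)
        z2, _ = standardize(table[["d", "b", "a", "c"]])
        _, s1 = fit_pca(z1, 2)
        _, s2 = fit_pca(z2, 2)
        np.testing.assert_allclose(s1, s2, atol=1e-8)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(9)
        z, _ = standardize(pd.DataFrame(rng.normal(size=(40, 5))))
        model, _ = fit_pca(z, 4)
        gram = model.components @ model.components.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-10)


class TestKMeans:
    def test_separable_blobs_recovered(self):
        rng = np.random.default_rng(10)
        x = np.vstack([rng.normal(0, 0.2, (30, 2)), rng.normal(5, 0.2, (30, 2))])
        res = kmeans_cluster(x, 2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_score(truth, res.labels) == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(8, 2))
        res = kmeans_cluster(x, 8, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(Exception):
            kmeans_cluster(np.zeros((3, 2)), 4)

    def test_every_cluster_nonempty(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(50, 3))
        res = kmeans_cluster(x, 5, seed=1)
        assert len(set(res.labels.tolist())) == 5

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(13)
        x = np.vstack([rng.normal(c, 0.3, (20, 2)) for c in (0, 4, 8)])
        perm = rng.permutation(len(x))
        l1 = kmeans_cluster(x, 3, seed=0).labels
        l2 = kmeans_cluster(x[perm], 3, seed=0).labels
        assert adjusted_rand_score(l1[perm], l2) == 1.0


class TestDBSCAN:
    def test_two_blobs_and_three_outliers(self):
        rng = np.random.default_rng(14)
        x = np.vstack([
            rng.normal(0, 0.1, (20, 2)),
            rng.normal(10, 0.1, (20, 2)),
            [[50, 50], [60, -60], [-70, 70]],
        ])
        labels = dbscan_cluster(x, eps=1.0, min_samples=4)
        assert len(set(labels.tolist()) - {-1}) == 2
        assert (labels == -1).sum() == 3

    def test_huge_eps_single_cluster_no_noise(self):
        rng = np.random.default_rng(15)
        labels = dbscan_cluster(rng.normal(size=(30, 2)), eps=1e6, min_samples=3)
        assert set(labels.tolist()) == {0}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            x = rng.normal(size=(100, 2))
            eps = float(rng.uniform(0.2, 0.8))
            ms = int(rng.integers(2, 8))
            ours = dbscan_cluster(x, eps, ms)
            ref = brute_dbscan(x, eps, ms)
            assert _partition(ours) == _partition(ref)
            np.testing.assert_array_equal(ours == -1, ref == -1)


class TestSilhouette:
    def test_far_separated_tight_clusters_approach_one(self):
        rng = np.random.default_rng(17)
        x = np.vstack([rng.normal(0, 1e-3, (15, 2)), rng.normal(1e4, 1e-3, (15, 2))])
        labels = np.repeat([0, 1], 15)
        assert silhouette(x, labels) == pytest.approx(1.0, abs=1e-4)

    def test_singleton_cluster_contributes_zero(self):
        x = np.array([[0.0, 0.0], [0.1, 0.0], [5.0, 5.0]])
        labels = np.array([0, 0, 1])
        assert silhouette(x, labels) == pytest.approx(
            brute_silhouette(x, labels), abs=1e-9
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(18)
        x = rng.normal(size=(200, 3))
        labels = rng.integers(0, 4, size=200)
        assert silhouette(x, labels) == pytest.approx(
            brute_silhouette(x, labels), abs=1e-9
        )

    def test_noise_points_excluded(self):
        rng = np.random.default_rng(19)
        x = np.vstack([rng.normal(0, 0.1, (10, 2)), rng.normal(5, 0.1, (10, 2))])
        labels = np.repeat([0, 1], 10)
        with_noise = np.concatenate([labels, [-1]])
        x_noise = np.vstack([x, [[100.0, 100.0]]])
        assert silhouette(x_noise, with_noise) == pytest.approx(
            silhouette(x, labels), abs=1e-12
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(DrugRecError):
            silhouette(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestSelectModel:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(20)
        x = rng.normal(size=(60, 2))
        best, board = select_model(x, kmeans_k_range=[3], dbscan_grid=())
        assert best.params == {"k": 3}
        assert len(board) == 1

    def test_leaderboard_is_bounded_by_winner(self):
        rng = np.random.default_rng(21)
        x = np.vstack([rng.normal(c, 0.3, (25, 2)) for c in (0, 5, 10)])
        best, board = select_model(
            x, kmeans_k_range=range(2, 6), dbscan_grid=((0.5, 3), (1.0, 3))
        )
        assert all(m.silhouette <= best.silhouette for m in board)

    def test_planted_blobs_recover_k(self):
        rng = np.random.default_rng(22)
        x = np.vstack([rng.normal(c * 6, 0.4, (40, 3)) for c in range(4)])
        best, _ = select_model(x, kmeans_k_range=range(2, 8), dbscan_grid=())
        assert best.n_clusters == 4


class TestAssignCluster:
    def _model(self, centroids):
        return ClusteringModel(
            algorithm="kmeans",
            params={"k": len(centroids)},
            labels=np.arange(len(centroids)),
            silhouette=0.5,
            seed=0,
            centroids=np.asarray(centroids, dtype=float),
        )

    def test_training_point_keeps_its_label(self):
        rng = np.random.default_rng(23)
        x = np.vstack([rng.normal(0, 0.2, (20, 2)), rng.normal(6, 0.2, (20, 2))])
        res = kmeans_cluster(x, 2, seed=0)
        model = self._model(res.centroids)
        np.testing.assert_array_equal(assign_cluster(model, x), res.labels)

    def test_equidistant_tie_goes_to_lowest_label(self):
        model = self._model([[0.0, 0.0], [2.0, 0.0]])
        assert assign_cluster(model, [[1.0, 0.0]])[0] == 0

    def test_perturbed_midpoint_switches(self):
        model = self._model([[0.0, 0.0], [2.0, 0.0], [1.0, 4.0]])
        assert assign_cluster(model, [[1.0, 3.0]])[0] == 2

    def test_dbscan_model_unsupported(self):
        model = ClusteringModel(
            algorithm="dbscan", params={}, labels=np.zeros(3), silhouette=0.1, seed=0
        )
        with pytest.raises(DrugRecError, match="dbscan"):
            assign_cluster(model, [[0.0, 0.0]])


class TestFittedPipeline:
    def test_json_round_trip_preserves_assignments(self, tmp_path):
        rng = np.random.default_rng(24)
        table = pd.DataFrame(
            np.vstack([rng.normal(0, 0.3, (30, 4)), rng.normal(5, 0.3, (30, 4))]),
            columns=list("abcd"),
        )
        pipe, _ = fit_cluster_pipeline(
            table, ClusterConfig(kmeans_k_range=(2, 3), dbscan_grid=())
        )
        path = tmp_path / "model.json"
        pipe.to_json(path)
        back = FittedClusterPipeline.from_json(path)
        np.testing.assert_array_equal(back.assign(table), pipe.assign(table))
        assert back.model.silhouette == pytest.approx(pipe.model.silhouette)

    def test_constant_columns_ignored(self):
        rng = np.random.default_rng(25)
        table = pd.DataFrame({
            "signal": np.concatenate([rng.normal(0, 0.1, 20), rng.normal(5, 0.1, 20)]),
            "noise": rng.normal(size=40),
            "flat": np.ones(40),
        })
        pipe, _ = fit_cluster_pipeline(
            table, ClusterConfig(pca_selector=1.0, kmeans_k_range=(2,), dbscan_grid=())
        )
        assert "flat" not in pipe.standardization.columns
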