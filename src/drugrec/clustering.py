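"""Patient grouping: standardisation, PCA, K-means/DBSCAN, silhouette selection.

Features are z-scored (population standard deviation, denominator n), reduced
with PCA — by default keeping the smallest number of components whose
cumulative explained-variance ratio reaches the target (0.62) — and clustered
in score space.  Candidate models (a K-means k-range and a DBSCAN
eps x min_samples grid) are ranked by the mean silhouette coefficient,
computed on the Euclidean metric over the PCA scores with DBSCAN noise points
excluded; ties break toward fewer clusters, then K-means over DBSCAN, then
the smaller parameter value.  Component signs are fixed so the
largest-magnitude loading of each component is positive, making scores
reproducible across runs and feature orderings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ConfigError, DrugRecError


@dataclass
class StandardizationParams:
    columns: list[str]
    mean: np.ndarray
    std: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        x = table[self.columns].to_numpy(dtype=float)
        return pd.DataFrame(
            (x - self.mean) / self.std, index=table.index, columns=self.columns
        )

    def inverse(self, z: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            z.to_numpy() * self.std + self.mean, index=z.index, columns=self.columns
        )


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, StandardizationParams]:
    """Z-score every column (population sd); error on zero-variance columns."""
    x = table.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0, ddof=0)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        names = [table.columns[i] for i in zero]
        raise DrugRecError(f"zero-variance columns cannot be standardized: {names}")
    params = StandardizationParams(list(table.columns), mean, std)
    return params.transform(table), params


@dataclass
class PCAModel:
    components: np.ndarray  # (k, p), rows orthonormal
    explained_variance_ratio: np.ndarray  # (k,)
    mean: np.ndarray  # (p,), column means of the training z-table
    columns: list[str]

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, z: pd.DataFrame) -> np.ndarray:
        x = z[self.columns].to_numpy(dtype=float) - self.mean
        return x @ self.components.T


def _fix_signs(components: np.ndarray) -> np.ndarray:
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_pca(
    z_table: pd.DataFrame, selector: float | int = 0.62
) -> tuple[PCAModel, np.ndarray]:
    """Fit PCA on a standardized table and return (model, score matrix).

    *selector* is either an integer (fixed number of components) or a float
    in (0, 1]: the smallest k whose cumulative explained-variance ratio
    reaches it.
    """
    if len(z_table) < 2:
        raise DrugRecError("PCA requires at least 2 rows")
    full = PCA(svd_solver="full").fit(z_table.to_numpy(dtype=float))
    ratios = full.explained_variance_ratio_
    if isinstance(selector, (int, np.integer)) and not isinstance(selector, bool):
        k = int(selector)
        if not 1 <= k <= len(ratios):
            raise ConfigError(f"component count {k} outside 1..{len(ratios)}")
    else:
        v = float(selector)
        if not 0 < v <= 1:
            raise ConfigError("cumulative-variance target must be in (0, 1]")
        k = int(np.searchsorted(np.cumsum(ratios), v - 1e-12) + 1)
        k = min(k, len(ratios))
    components = _fix_signs(full.components_[:k])
    model = PCAModel(
        components=components,
        explained_variance_ratio=ratios[:k].copy(),
        mean=full.mean_.copy(),
        columns=list(z_table.columns),
    )
    return model, model.transform(z_table)


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float


def kmeans_cluster(
    scores: np.ndarray,
    k: int,
    seed: int = 42,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
) -> KMeansResult:
    """K-means with k-means++ initialisation, best of *n_init* restarts."""
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if k > len(scores):
        raise ConfigError(f"k={k} exceeds number of points {len(scores)}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(scores)
    return KMeansResult(
        labels=km.labels_.astype(int),
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
    )


def dbscan_cluster(
    scores: np.ndarray, eps: float, min_samples: int
) -> np.ndarray:
    """Density clustering; a core point has >= min_samples neighbours within
    eps (itself included); points reachable from no core point get label -1."""
    if eps <= 0:
        raise ConfigError("eps must be > 0")
    if min_samples < 1:
        raise ConfigError("min_samples must be >= 1")
    return DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        np.asarray(scores, dtype=float)
    )


def silhouette(
    scores: np.ndarray,
    labels: np.ndarray,
    max_exact: int = 20000,
    seed: int = 0,
) -> float:
    """Mean silhouette coefficient over non-noise points (Euclidean).

    Noise points (label -1) are excluded.  Above *max_exact* points a seeded
    subsample of that size is scored instead (the pairwise-distance cost is
    quadratic).  Singleton clusters contribute 0, the standard convention.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    mask = labels != -1
    scores, labels = scores[mask], labels[mask]
    if len(np.unique(labels)) < 2:
        raise DrugRecError("silhouette requires at least 2 clusters")
    if len(scores) > max_exact:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(scores), size=max_exact, replace=False)
        scores, labels = scores[idx], labels[idx]
        if len(np.unique(labels)) < 2:
            raise DrugRecError("subsample collapsed to a single cluster")
    return float(silhouette_score(scores, labels, metric="euclidean"))


@dataclass
class ClusteringModel:
    """A fitted clustering in PCA-score space plus its quality score."""

    algorithm: str  # "kmeans" | "dbscan"
    params: dict
    labels: np.ndarray
    silhouette: float
    seed: int
    centroids: np.ndarray | None = None  # kmeans only

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.tolist()) - {-1})


def _candidate_sort_key(model: ClusteringModel):
    alg_rank = 0 if model.algorithm == "kmeans" else 1
    if model.algorithm == "kmeans":
        param_key = (model.params["k"],)
    else:
        param_key = (model.params["eps"], model.params["min_samples"])
    return (-model.silhouette, model.n_clusters, alg_rank, param_key)


def select_model(
    scores: np.ndarray,
    kmeans_k_range: Sequence[int] = range(2, 11),
    dbscan_grid: Sequence[tuple[float, int]] = (),
    seed: int = 42,
    silhouette_max_exact: int = 20000,
) -> tuple[ClusteringModel, list[ClusteringModel]]:
    """Fit every candidate, score by silhouette, return (best, leaderboard).

    Candidates that degenerate to fewer than two clusters are scored as
    invalid and skipped.  Ties break toward fewer clusters, then K-means
    over DBSCAN, then the lower parameter value.
    """
    scores = np.asarray(scores, dtype=float)
    candidates: list[ClusteringModel] = []
    for k in kmeans_k_range:
        res = kmeans_cluster(scores, k, seed=seed)
        sil = silhouette(scores, res.labels, max_exact=silhouette_max_exact, seed=seed)
        candidates.append(
            ClusteringModel(
                algorithm="kmeans",
                params={"k": int(k)},
                labels=res.labels,
                silhouette=sil,
                seed=seed,
                centroids=res.centroids,
            )
        )
    for eps, min_samples in dbscan_grid:
        labels = dbscan_cluster(scores, eps, min_samples)
        non_noise = set(labels.tolist()) - {-1}
        if len(non_noise) < 2:
            continue
        sil = silhouette(scores, labels, max_exact=silhouette_max_exact, seed=seed)
        candidates.append(
            ClusteringModel(
                algorithm="dbscan",
                params={"eps": float(eps), "min_samples": int(min_samples)},
                labels=labels,
                silhouette=sil,
                seed=seed,
            )
        )
    if not candidates:
        raise DrugRecError("every candidate clustering was degenerate")
    leaderboard = sorted(candidates, key=_candidate_sort_key)
    return leaderboard[0], leaderboard


def assign_cluster(model: ClusteringModel, points: np.ndarray) -> np.ndarray:
    """Nearest-centroid label for new points (K-means models only).

    Ties go to the lowest label.
    """
    if model.centroids is None:
        raise DrugRecError(
            f"cluster assignment unsupported for '{model.algorithm}' (no centroids)"
        )
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(points[:, None, :] - model.centroids[None, :, :], axis=2)
    return np.argmin(d, axis=1)


@dataclass
class ClusterConfig:
    """Search spaces and numerical settings for patient grouping."""

    pca_selector: float | int = 0.62
    kmeans_k_range: tuple[int, ...] = tuple(range(2, 11))
    dbscan_grid: tuple[tuple[float, int], ...] = tuple(
        (eps, m) for eps in (0.3, 0.5, 0.8, 1.2, 2.0) for m in (5, 10, 20)
    )
    seed: int = 42
    silhouette_max_exact: int = 20000


@dataclass
class FittedClusterPipeline:
    """Standardisation + PCA + clustering, the persisted grouping model."""

    standardization: StandardizationParams
    pca: PCAModel
    model: ClusteringModel

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        return self.pca.transform(self.standardization.transform(features))

    def assign(self, features: pd.DataFrame) -> np.ndarray:
        return assign_cluster(self.model, self.transform(features))

    def to_json(self, path) -> None:
        doc = {
            "standardization": {
                "columns": self.standardization.columns,
                "mean": self.standardization.mean.tolist(),
                "std": self.standardization.std.tolist(),
            },
            "pca": {
                "components": self.pca.components.tolist(),
                "explained_variance_ratio": self.pca.explained_variance_ratio.tolist(),
                "mean": self.pca.mean.tolist(),
                "columns": self.pca.columns,
            },
            "clustering": {
                "algorithm": self.model.algorithm,
                "params": self.model.params,
                "labels": self.model.labels.tolist(),
                "silhouette": self.model.silhouette,
                "seed": self.model.seed,
                "centroids": None
                if self.model.centroids is None
                else self.model.centroids.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path) -> "FittedClusterPipeline":
        with open(path) as fh:
            doc = json.load(fh)
        s = doc["standardization"]
        p = doc["pca"]
        c = doc["clustering"]
        return cls(
            standardization=StandardizationParams(
                s["columns"], np.array(s["mean"]), np.array(s["std"])
            ),
            pca=PCAModel(
                components=np.array(p["components"]),
                explained_variance_ratio=np.array(p["explained_variance_ratio"]),
                mean=np.array(p["mean"]),
                columns=p["columns"],
            ),
            model=ClusteringModel(
                algorithm=c["algorithm"],
                params=c["params"],
                labels=np.array(c["labels"], dtype=int),
                silhouette=c["silhouette"],
                seed=c["seed"],
                centroids=None
                if c["centroids"] is None
                else np.array(c["centroids"]),
            ),
        )


def fit_cluster_pipeline(
    table: pd.DataFrame, config: ClusterConfig | None = None
) -> tuple[FittedClusterPipeline, list[ClusteringModel]]:
    """Standardize -> PCA -> model selection on a numeric patient table.

    Zero-variance columns carry no grouping information and are removed
    before standardisation (the fitted pipeline remembers which columns it
    uses, so transform/assign accept the full table).
    """
    cfg = config or ClusterConfig()
    varying = table.columns[table.std(ddof=0) > 0]
    if len(varying) == 0:
        raise DrugRecError("every feature column is constant")
    table = table[varying]
    z, std_params = standardize(table)
    pca_model, scores = fit_pca(z, cfg.pca_selector)
    best, leaderboard = select_model(
        scores,
        kmeans_k_range=cfg.kmeans_k_range,
        dbscan_grid=cfg.dbscan_grid,
        seed=cfg.seed,
        silhouette_max_exact=cfg.silhouette_max_exact,
    )
    return (
        FittedClusterPipeline(
            standardization=std_params, pca=pca_model, model=best
        ),
        leaderboard,
    )
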