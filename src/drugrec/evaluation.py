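"""Held-out evaluation of the recommender: 80/20 patient split, MSE, precision@N.

Patients (never individual cells) are split into train and test.  The
grouping model is fitted on training patients' features; each test patient
is assigned the nearest K-means centroid from their clinical features alone
— the cold-start route, their ratings play no part in cluster assignment.

Prediction quality (MSE): for every test patient and every drug the patient
actually received (observed rating > 0), the dose value is predicted from
training patients in the assigned cluster; MSE averages the squared errors
over those cells.  Predicting true zeros is excluded — a zero means "not
prescribed", not a dose of zero.

Recommendation quality (precision@N): a drug is *relevant* when its observed
dose value exceeds 1, i.e. the dose was increased.  For each test patient
with at least one relevant drug, the top-N list is computed from training
data only and patient precision is |recommended ∩ relevant| / N; the report
gives the mean over those patients and counts the excluded ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .clustering import ClusterConfig, FittedClusterPipeline, fit_cluster_pipeline
from .errors import ConfigError, DrugRecError
from .preprocess import FeatureTableResult, PreprocessConfig, build_feature_table
from .recommender import RatingMatrix, build_rating_matrix, predict_for_query
from .synthetic import SyntheticConfig, generate_encounters


@dataclass
class EvalConfig:
    train_fraction: float = 0.80
    seed: int = 0
    top_n: int = 3
    relevance_threshold: float = 1.0  # strict ">"

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if self.top_n < 1:
            raise ConfigError("top_n must be >= 1")


def split_patients(
    patients: pd.Index | RatingMatrix, config: EvalConfig | None = None
) -> tuple[pd.Index, pd.Index]:
    """Seeded uniform split by patient; returns (train ids, test ids).

    Sizes are round(train_fraction * n) and the remainder; e.g. 5177
    patients at 0.80 split 4142 / 1035.
    """
    cfg = config or EvalConfig()
    index = patients.patients if isinstance(patients, RatingMatrix) else patients
    n = len(index)
    if n < 2:
        raise DrugRecError("need at least 2 patients to split")
    n_train = int(round(cfg.train_fraction * n))
    if n_train == 0 or n_train == n:
        raise DrugRecError(
            f"split {cfg.train_fraction} of {n} leaves an empty partition"
        )
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    return index[np.sort(perm[:n_train])], index[np.sort(perm[n_train:])]


def evaluate_predictions(
    train: RatingMatrix, test: RatingMatrix, config: EvalConfig | None = None
) -> dict:
    """MSE of predicted vs observed dose values on nonzero test cells.

    *test* must already carry assigned cluster labels (nearest centroid on
    features).  Test ratings drive similarity only; all neighbour ratings
    come from *train*.
    """
    pred, _ = predict_for_query(train, test.ratings, test.clusters)
    observed = test.ratings.to_numpy()
    mask = observed > 0
    if not mask.any():
        raise DrugRecError("no observed nonzero test cells to evaluate")
    errors = (pred.to_numpy() - observed) ** 2
    per_cluster = {}
    clusters = test.clusters.to_numpy()
    for c in np.unique(clusters):
        cmask = mask & (clusters[:, None] == c)
        if cmask.any():
            per_cluster[int(c)] = float(errors[cmask].mean())
    return {
        "mse": float(errors[mask].mean()),
        "n_cells": int(mask.sum()),
        "per_cluster_mse": per_cluster,
    }


def evaluate_recommendations(
    train: RatingMatrix, test: RatingMatrix, config: EvalConfig | None = None
) -> dict:
    """Mean precision of top-N recommendations over evaluable test patients."""
    cfg = config or EvalConfig()
    pred, prov = predict_for_query(train, test.ratings, test.clusters)
    drugs = np.array(train.drugs)
    observed = test.ratings.to_numpy()
    relevant = observed > cfg.relevance_threshold

    precisions = []
    per_cluster: dict[int, list[float]] = {}
    n_no_relevant = 0
    for i in range(len(test.patients)):
        rel = set(drugs[relevant[i]])
        if not rel:
            n_no_relevant += 1
            continue
        scores = pred.iloc[i]
        prow = prov.iloc[i]
        # Same ranking rule as recommend_top_n: global-mean fallbacks are a
        # cohort prior, ranked below cluster-backed scores.
        top = sorted(
            drugs, key=lambda d: (prow[d] == "global_mean", -scores[d], d)
        )[: cfg.top_n]
        p = len(rel.intersection(top)) / cfg.top_n
        precisions.append(p)
        per_cluster.setdefault(int(test.clusters.iloc[i]), []).append(p)
    if not precisions:
        raise DrugRecError("no test patient has a relevant drug")
    return {
        "precision": float(np.mean(precisions)),
        "n_evaluated": len(precisions),
        "n_no_relevant": n_no_relevant,
        "per_cluster_precision": {
            c: float(np.mean(v)) for c, v in sorted(per_cluster.items())
        },
    }


@dataclass
class EvalReport:
    """Full experiment report, serialisable to JSON."""

    n_train: int
    n_test: int
    mse: float
    n_mse_cells: int
    precision: float
    n_precision_patients: int
    n_no_relevant: int
    per_cluster_mse: Mapping[int, float]
    per_cluster_precision: Mapping[int, float]
    algorithm: str
    n_clusters: int
    silhouette: float
    pca_components: int
    explained_variance: float
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        doc = asdict(self)
        doc["per_cluster_mse"] = {str(k): v for k, v in doc["per_cluster_mse"].items()}
        doc["per_cluster_precision"] = {
            str(k): v for k, v in doc["per_cluster_precision"].items()
        }
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def evaluate_split(
    features: pd.DataFrame,
    drug_ratings: pd.DataFrame,
    eval_config: EvalConfig | None = None,
    cluster_config: ClusterConfig | None = None,
) -> tuple[EvalReport, FittedClusterPipeline]:
    """Split patients, fit grouping on train, assign test, score MSE and
    precision.  *features* and *drug_ratings* share a patient index; the
    clustering view is their concatenation."""
    cfg = eval_config or EvalConfig()
    ccfg = cluster_config or ClusterConfig()
    train_ids, test_ids = split_patients(features.index, cfg)

    full = pd.concat([features, drug_ratings], axis=1)
    pipeline, leaderboard = fit_cluster_pipeline(full.loc[train_ids], ccfg)
    if pipeline.model.centroids is None:
        # Held-out patients need nearest-centroid assignment, so the CF stage
        # carries the best centroid-bearing (K-means) candidate forward.
        kmeans = [m for m in leaderboard if m.centroids is not None]
        if not kmeans:
            raise DrugRecError("no centroid-bearing clustering candidate available")
        pipeline.model = kmeans[0]

    train_labels = pd.Series(pipeline.model.labels, index=train_ids)
    test_labels = pd.Series(pipeline.assign(full.loc[test_ids]), index=test_ids)
    train = build_rating_matrix(drug_ratings.loc[train_ids], train_labels)
    test = build_rating_matrix(drug_ratings.loc[test_ids], test_labels)

    mse_part = evaluate_predictions(train, test, cfg)
    prec_part = evaluate_recommendations(train, test, cfg)
    report = EvalReport(
        n_train=len(train_ids),
        n_test=len(test_ids),
        mse=mse_part["mse"],
        n_mse_cells=mse_part["n_cells"],
        precision=prec_part["precision"],
        n_precision_patients=prec_part["n_evaluated"],
        n_no_relevant=prec_part["n_no_relevant"],
        per_cluster_mse=mse_part["per_cluster_mse"],
        per_cluster_precision=prec_part["per_cluster_precision"],
        algorithm=pipeline.model.algorithm,
        n_clusters=pipeline.model.n_clusters,
        silhouette=pipeline.model.silhouette,
        pca_components=pipeline.pca.k,
        explained_variance=float(pipeline.pca.explained_variance_ratio.sum()),
        seed=cfg.seed,
        config={
            "train_fraction": cfg.train_fraction,
            "top_n": cfg.top_n,
            "relevance_threshold": cfg.relevance_threshold,
        },
    )
    return report, pipeline


def run_evaluation(
    raw: pd.DataFrame | None = None,
    synthetic_config: SyntheticConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    cluster_config: ClusterConfig | None = None,
    eval_config: EvalConfig | None = None,
    seed: int | None = None,
) -> EvalReport:
    """Single seeded entry point for the whole experiment.

    Either pass a raw encounter table or let the synthetic generator produce
    one.  *seed*, when given, overrides both the generator seed and the
    split seed.
    """
    if raw is None:
        scfg = synthetic_config or SyntheticConfig()
        if seed is not None:
            scfg = _with_seed(scfg, seed)
        raw, _ = generate_encounters(scfg)
    ecfg = eval_config or EvalConfig()
    if seed is not None:
        ecfg = EvalConfig(
            train_fraction=ecfg.train_fraction,
            seed=seed,
            top_n=ecfg.top_n,
            relevance_threshold=ecfg.relevance_threshold,
        )
    result: FeatureTableResult = build_feature_table(raw, preprocess_config)
    report, _ = evaluate_split(
        result.features, result.drug_ratings, ecfg, cluster_config
    )
    return report


def _with_seed(cfg: SyntheticConfig, seed: int) -> SyntheticConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed)
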