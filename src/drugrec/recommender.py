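"""Cluster-restricted user-based collaborative filtering over dose ratings.

Patients are users, drugs are items, and the encoded dose-change values are
the ratings: 0 = not administered, 1 = dose decreased (and, by default,
steady), 2 = dose increased.  A patient's unknown cell for a drug is
predicted as the cosine-similarity-weighted mean of the ratings of patients
in the *same cluster* who actually received that drug:

    r_hat(u, d) = sum_v sim(u, v) * r(v, d) / sum_v sim(u, v)

with v ranging over same-cluster patients (v != u) having r(v, d) > 0 and
sim(u, v) > 0.  Similarity is the cosine of the full rating rows, zeros
included — the matrix is dense by construction, a 0 is an observed
"not administered".  Ratings are not mean-centered: on a 3-level ordinal
scale where 0 means "not administered", subtracting user means would
conflate prescription breadth with dose direction.

When a patient has no qualifying neighbour the prediction falls back to the
mean nonzero rating of the drug within the cluster, then to the global mean
nonzero rating; the provenance flag records which branch produced each
value.  Restricting neighbourhoods to the patient's cluster is what lets a
new patient — clustered on clinical characteristics alone — receive
recommendations before accumulating any rating history.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DrugRecError, SchemaError
from .schema import _atomic_to_csv

logger = logging.getLogger(__name__)

PROVENANCE_NEIGHBORS = "neighbors"
PROVENANCE_CLUSTER_MEAN = "cluster_mean"
PROVENANCE_GLOBAL_MEAN = "global_mean"
PROVENANCE_OBSERVED = "observed"


@dataclass
class RatingMatrix:
    """Patients x drugs matrix of encoded doses plus per-patient cluster labels."""

    ratings: pd.DataFrame  # index: patient ids, columns: drug names, float
    clusters: pd.Series  # same index, integer labels

    def __post_init__(self):
        self.clusters = self.clusters.reindex(self.ratings.index)
        if self.clusters.isna().any():
            missing = self.ratings.index[self.clusters.isna()].tolist()[:5]
            raise SchemaError(f"patients without cluster label: {missing}")
        self.clusters = self.clusters.astype(int)
        if (self.ratings.to_numpy() < 0).any():
            raise SchemaError("negative ratings are not allowed")

    @property
    def patients(self) -> pd.Index:
        return self.ratings.index

    @property
    def drugs(self) -> list[str]:
        return list(self.ratings.columns)

    def subset(self, patients: Iterable) -> "RatingMatrix":
        idx = pd.Index(patients)
        return RatingMatrix(self.ratings.loc[idx], self.clusters.loc[idx])

    def to_csv(self, path) -> None:
        out = self.ratings.copy()
        out["cluster"] = self.clusters
        out.index.name = out.index.name or "patient_id"
        _atomic_to_csv(out, path, index=True)

    @classmethod
    def from_csv(cls, path) -> "RatingMatrix":
        df = pd.read_csv(path, index_col=0)
        if "cluster" not in df.columns:
            raise SchemaError("rating matrix CSV lacks a 'cluster' column")
        clusters = df.pop("cluster")
        return cls(df.astype(float), clusters)


def build_rating_matrix(
    drug_ratings: pd.DataFrame, cluster_labels: pd.Series | np.ndarray
) -> RatingMatrix:
    """Attach cluster labels to an encoded per-patient drug table."""
    if not isinstance(cluster_labels, pd.Series):
        cluster_labels = pd.Series(
            np.asarray(cluster_labels), index=drug_ratings.index
        )
    return RatingMatrix(drug_ratings.astype(float), cluster_labels)


def cosine_similarity(u, v) -> float:
    """Cosine of two rating vectors; 0 if either vector is all zeros."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class Prediction:
    patient: object
    drug: str
    value: float
    provenance: str


def _cosine_rows(queries: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity, rows of *queries* vs rows of *base*;
    zero rows yield similarity 0."""
    qn = np.linalg.norm(queries, axis=1)
    bn = np.linalg.norm(base, axis=1)
    denom = np.outer(qn, bn)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(denom > 0, queries @ base.T / np.where(denom == 0, 1, denom), 0.0)
    return sims


def _nonzero_mean(values: np.ndarray) -> float:
    nz = values[values > 0]
    return float(nz.mean()) if nz.size else math.nan


def predict_for_query(
    matrix: RatingMatrix,
    query_ratings: pd.DataFrame,
    query_clusters: pd.Series | np.ndarray,
    exclude_self: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict every drug for every query patient from *matrix* (training data).

    *query_ratings* supplies the query rows (aligned to the training drug
    columns); its values drive similarity only — predictions are weighted
    means of training ratings.  When *exclude_self* and a query index also
    appears in the training matrix, that training row is removed from its
    own neighbourhood.

    Returns (predictions, provenance), both patients x drugs frames.
    """
    drugs = matrix.drugs
    q = query_ratings[drugs].to_numpy(dtype=float)
    if not isinstance(query_clusters, pd.Series):
        query_clusters = pd.Series(
            np.asarray(query_clusters), index=query_ratings.index
        )
    r_all = matrix.ratings.to_numpy(dtype=float)
    global_means = np.array([_nonzero_mean(r_all[:, j]) for j in range(len(drugs))])

    pred = np.full((len(q), len(drugs)), np.nan)
    prov = np.full((len(q), len(drugs)), PROVENANCE_GLOBAL_MEAN, dtype=object)
    train_clusters = matrix.clusters.to_numpy()
    train_index = matrix.patients

    for cluster in np.unique(query_clusters.to_numpy()):
        q_rows = np.flatnonzero(query_clusters.to_numpy() == cluster)
        t_rows = np.flatnonzero(train_clusters == cluster)
        r_c = r_all[t_rows]
        cluster_means = (
            np.array([_nonzero_mean(r_c[:, j]) for j in range(len(drugs))])
            if len(t_rows)
            else np.full(len(drugs), np.nan)
        )
        if len(t_rows):
            sims = _cosine_rows(q[q_rows], r_c)
            if exclude_self:
                t_pos = {train_index[t]: i for i, t in enumerate(t_rows)}
                for qi, q_idx in enumerate(q_rows):
                    pid = query_ratings.index[q_idx]
                    if pid in t_pos:
                        sims[qi, t_pos[pid]] = 0.0
            sims = np.clip(sims, 0.0, None)
            mask = (r_c > 0).astype(float)
            num = sims @ (r_c * mask)
            den = sims @ mask
            with np.errstate(invalid="ignore", divide="ignore"):
                weighted = np.where(den > 0, num / den, np.nan)
        else:
            weighted = np.full((len(q_rows), len(drugs)), np.nan)

        for qi, q_idx in enumerate(q_rows):
            for j in range(len(drugs)):
                if len(t_rows) and weighted[qi, j] == weighted[qi, j]:
                    pred[q_idx, j] = weighted[qi, j]
                    prov[q_idx, j] = PROVENANCE_NEIGHBORS
                elif cluster_means[j] == cluster_means[j]:
                    pred[q_idx, j] = cluster_means[j]
                    prov[q_idx, j] = PROVENANCE_CLUSTER_MEAN
                elif global_means[j] == global_means[j]:
                    pred[q_idx, j] = global_means[j]
                    prov[q_idx, j] = PROVENANCE_GLOBAL_MEAN
                else:
                    # No nonzero rating for this drug anywhere: no evidence,
                    # score 0 so it can never be recommended.
                    pred[q_idx, j] = 0.0
                    prov[q_idx, j] = PROVENANCE_GLOBAL_MEAN

    return (
        pd.DataFrame(pred, index=query_ratings.index, columns=drugs),
        pd.DataFrame(prov, index=query_ratings.index, columns=drugs),
    )


def predict_rating(matrix: RatingMatrix, patient, drug: str) -> Prediction:
    """Predict one (patient, drug) cell from the patient's cluster."""
    if patient not in matrix.patients:
        raise DrugRecError(f"unknown patient: {patient!r}")
    if drug not in matrix.drugs:
        raise DrugRecError(f"unknown drug: {drug!r}")
    row = matrix.ratings.loc[[patient]]
    cluster = matrix.clusters.loc[[patient]]
    pred, prov = predict_for_query(matrix, row, cluster, exclude_self=True)
    return Prediction(
        patient=patient,
        drug=drug,
        value=float(pred.loc[patient, drug]),
        provenance=str(prov.loc[patient, drug]),
    )


def complete_matrix(matrix: RatingMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill every zero cell with its prediction; observed cells unchanged.

    Returns (completed ratings, provenance) frames; provenance is
    ``"observed"`` where the original cell was nonzero.
    """
    pred, prov = predict_for_query(
        matrix, matrix.ratings, matrix.clusters, exclude_self=True
    )
    observed = matrix.ratings.to_numpy() > 0
    completed = np.where(observed, matrix.ratings.to_numpy(), pred.to_numpy())
    prov_arr = np.where(observed, PROVENANCE_OBSERVED, prov.to_numpy())
    return (
        pd.DataFrame(completed, index=matrix.patients, columns=matrix.drugs),
        pd.DataFrame(prov_arr, index=matrix.patients, columns=matrix.drugs),
    )


@dataclass
class RecommendationList:
    patient: object
    items: list[tuple[str, float, str]]  # (drug, score, provenance), score desc

    @property
    def drugs(self) -> list[str]:
        return [d for d, _, _ in self.items]


def _top_n_from_scores(
    patient, scores: pd.Series, provenance: pd.Series, n: int
) -> RecommendationList:
    if n > len(scores):
        logger.warning(
            "top-%d requested but only %d drugs available; returning all",
            n,
            len(scores),
        )
        n = len(scores)
    # A global-mean fallback is a cohort-wide prior, not cluster evidence:
    # it ranks below any score backed by the patient's own cluster.
    order = sorted(
        scores.index,
        key=lambda d: (provenance[d] == PROVENANCE_GLOBAL_MEAN, -scores[d], d),
    )[:n]
    return RecommendationList(
        patient=patient,
        items=[(d, float(scores[d]), str(provenance[d])) for d in order],
    )


def recommend_top_n(
    matrix: RatingMatrix, patient, n: int = 3, use_predicted: bool = True
) -> RecommendationList:
    """Top-*n* drugs for a training patient, highest score first.

    With *use_predicted* (default) zero cells are scored by their cluster
    prediction and observed cells keep their observed dose value; otherwise
    only observed values rank.  Already-administered drugs are not excluded.
    Ties break alphabetically by drug name.
    """
    if n < 1:
        raise DrugRecError("n must be >= 1")
    if patient not in matrix.patients:
        raise DrugRecError(f"unknown patient: {patient!r}")
    if use_predicted:
        completed, prov = complete_matrix(matrix)
        scores = completed.loc[patient]
        provenance = prov.loc[patient]
    else:
        scores = matrix.ratings.loc[patient]
        provenance = pd.Series(PROVENANCE_OBSERVED, index=matrix.ratings.columns)
    return _top_n_from_scores(patient, scores, provenance, n)


def recommend_for_new(
    matrix: RatingMatrix,
    rating_row: pd.Series,
    cluster_label: int,
    n: int = 3,
) -> RecommendationList:
    """Top-*n* drugs for a patient outside the training matrix.

    The new patient's (possibly all-zero) rating row drives similarity;
    every drug is scored by its cluster prediction from training data.
    """
    q = pd.DataFrame([rating_row.reindex(matrix.drugs).fillna(0.0)], index=["__new__"])
    pred, prov = predict_for_query(
        matrix, q, pd.Series([cluster_label], index=["__new__"]), exclude_self=False
    )
    return _top_n_from_scores("__new__", pred.iloc[0], prov.iloc[0], n)
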