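"""k-means pseudo-labels over feature vectors.

The triplet embedder needs a notion of "similar set" for every entity;
clustering the feature vectors supplies it: co-cluster members are the
similar set, everything else the dissimilar set.  The cluster count is
scanned and chosen so that clusters come out roughly equal in size,
operationalized as the minimal coefficient of variation of cluster
sizes (ties broken toward smaller k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import ValidationError
from .preprocess import FeatureMatrix

__all__ = ["ClusterAssignment", "assign_cluster_labels", "select_cluster_count"]

#: k-means restarts per k; best inertia kept, all seeded from the master seed
N_RESTARTS = 10


@dataclass
class ClusterAssignment:
    """Pseudo-labels produced by seeded k-means."""

    labels: np.ndarray
    k: int
    inertia: float
    seed: int


def _as_array(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return np.asarray(features.values, dtype=float)
    return np.asarray(features, dtype=float)


def _fill_empty_clusters(F, labels, k):
    """Deterministically repopulate empty clusters.

    For each empty cluster, steal the point farthest from the centroid
    of its current (multi-member) cluster.  Guarantees every label in
    0..k-1 occurs whenever the data has at least k rows.
    """
    labels = labels.copy()
    for c in range(k):
        if np.any(labels == c):
            continue
        counts = np.bincount(labels, minlength=k)
        donors = np.flatnonzero(counts[labels] > 1)
        if donors.size == 0:
            break
        centroids = np.zeros((k, F.shape[1]))
        for j in range(k):
            member = labels == j
            if member.any():
                centroids[j] = F[member].mean(axis=0)
        dist = np.linalg.norm(F[donors] - centroids[labels[donors]], axis=1)
        labels[donors[np.argmax(dist)]] = c
    return labels


def assign_cluster_labels(features, k: int, seed: int) -> ClusterAssignment:
    """Seeded k-means with k-means++ initialization and 10 restarts.

    Deterministic for fixed (features, k, seed).  Empty clusters after
    convergence (possible only when the data has fewer than k distinct
    rows) are refilled at the farthest point of an over-full cluster.
    """
    F = _as_array(features)
    if not (1 <= k <= F.shape[0]):
        raise ValidationError(f"k={k} outside 1..{F.shape[0]}")
    km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-row ConvergenceWarning
        labels = km.fit_predict(F)
    if np.unique(labels).size < k:
        labels = _fill_empty_clusters(F, labels, k)
        centroids = np.vstack([F[labels == c].mean(axis=0) for c in range(k)])
        inertia = float(np.sum((F - centroids[labels]) ** 2))
    else:
        inertia = float(km.inertia_)
    return ClusterAssignment(labels=labels, k=k, inertia=inertia, seed=seed)


def balance_score(labels, k: int) -> float:
    """Coefficient of variation of cluster sizes (population std / mean)."""
    sizes = np.bincount(labels, minlength=k).astype(float)
    return float(np.std(sizes) / np.mean(sizes))


def select_cluster_count(features, k_min: int, k_max: int, seed: int) -> int:
    """Pick the k in [k_min, k_max] whose clusters are most equal in size.

    For each k the balance score is the coefficient of variation of the
    k-means cluster sizes; the minimizing k wins, ties going to the
    smaller k.  Deterministic for a fixed seed.
    """
    F = _as_array(features)
    if not (2 <= k_min <= k_max <= F.shape[0]):
        raise ValidationError(
            f"need 2 <= k_min <= k_max <= {F.shape[0]}, got [{k_min}, {k_max}]"
        )
    ks = np.arange(k_min, k_max + 1)
    scores = np.array([
        balance_score(assign_cluster_labels(F, int(k), seed).labels, int(k))
        for k in ks
    ])
    return int(ks[int(np.argmin(scores))])
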