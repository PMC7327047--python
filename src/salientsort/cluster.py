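"""Offline unsupervised labeling of training spikes.

k-means on the raw K-dimensional waveforms, with the number of units chosen
by maximizing the mean silhouette over a small k range (2-4 by default,
matching typical per-channel unit counts in cortical array recordings).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .datatypes import SpikeMatrix
from .errors import ParameterError


@dataclass
class ClusteringResult:
    labels: np.ndarray
    k: int
    silhouette_by_k: dict[int, float]
    centroids: np.ndarray

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "labels": self.labels.astype(int).tolist(),
            "silhouette_by_k": {str(k): float(v) for k, v in self.silhouette_by_k.items()},
            "centroids": self.centroids.tolist(),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def kmeans_cluster(
    matrix: SpikeMatrix,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Euclidean k-means on raw waveforms.

    k-means++ initialization, best of ``n_restarts`` by inertia, Lloyd
    iterations to relative inertia change < 1e-6 (at most 300 iterations).
    Returns ``(labels, centroids, inertia)``.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if matrix.n_spikes < k:
        raise ParameterError(f"{matrix.n_spikes} spikes cannot form {k} clusters")
    X = matrix.waveforms.astype(float)
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    ).fit(X)
    return km.labels_.astype(int), km.cluster_centers_, float(km.inertia_)


def silhouette_score(matrix: SpikeMatrix, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouettes s = (b - a) / max(a, b) and their mean.

    ``a`` is the mean intra-cluster distance excluding the point itself;
    ``b`` the smallest mean distance to any other cluster.  Degenerate
    conventions: 0/0 -> 0, and points in singleton clusters get s = 0.
    """
    labels = np.asarray(labels)
    X = matrix.waveforms.astype(float)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ParameterError("silhouette requires at least 2 clusters")
    D = cdist(X, X)
    n = X.shape[0]
    s = np.zeros(n)
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    for idx in range(n):
        own = members[labels[idx]]
        if own.size == 1:
            s[idx] = 0.0
            continue
        a = D[idx, own].sum() / (own.size - 1)
        b = min(D[idx, members[c]].mean() for c in uniq if c != labels[idx])
        denom = max(a, b)
        s[idx] = 0.0 if denom == 0 else (b - a) / denom
    return s, float(s.mean())


def cluster_channel(
    matrix: SpikeMatrix,
    k_min: int = 2,
    k_max: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusteringResult:
    """Cluster one channel, choosing k in [k_min, k_max] by mean silhouette.

    Ties go to the smaller k.
    """
    if not 2 <= k_min <= k_max <= matrix.n_spikes - 1:
        raise ParameterError("require 2 <= k_min <= k_max <= n_spikes - 1")
    results = {}
    sil_by_k: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels, centroids, _ = kmeans_cluster(matrix, k, n_restarts, seed)
        _, mean_sil = silhouette_score(matrix, labels)
        results[k] = (labels, centroids)
        sil_by_k[k] = mean_sil
    best_k = max(sorted(sil_by_k), key=lambda k: sil_by_k[k])
    labels, centroids = results[best_k]
    return ClusteringResult(
        labels=labels, k=best_k, silhouette_by_k=sil_by_k, centroids=centroids
    )
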