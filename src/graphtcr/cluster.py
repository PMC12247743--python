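"""Density-based repertoire clustering and purity metrics.

TCR embeddings are reduced (PCA to 24 dimensions by default, or classical
MDS when the input is a precomputed distance matrix) and clustered with
DBSCAN across a sweep of neighborhood radii ε (default 0.01–20, Manhattan
metric).  Clusterings are scored against epitope labels with two metrics:

* c-Precision of cluster C_i: max_j |C_i ∩ L_j| / |C_i| — the purity of
  the cluster with respect to its best-matching epitope label L_j.
* c-CSI: Σ_i max_j |C_i ∩ L_j| / (Σ_i |C_i| + Σ_j |L_j| − Σ_i max_j |C_i ∩ L_j|)
  — a critical-success-index that penalizes both impure clusters and
  points left unclustered (noise counts in Σ_j |L_j| but not Σ_i |C_i|).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import PCA

NOISE = -1


@dataclass
class ClusterConfig:
    epsilon: float = 1.0
    min_points: int = 5
    metric: str = "manhattan"  # manhattan | euclidean
    reduction: str = "pca"     # pca | mds | none
    reduced_dims: int = 24

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.metric not in ("manhattan", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class ClusterResult:
    assignments: np.ndarray  # cluster id per point, NOISE (-1) for noise
    n_clusters: int


@dataclass
class ClusterMetrics:
    per_cluster_precision: dict[int, float]
    mean_precision: float            # size-weighted
    mean_precision_unweighted: float
    c_csi: float
    n_clusters: int = 0
    noise_fraction: float = 0.0


def reduce_pca(X: np.ndarray, n: int) -> np.ndarray:
    """Top-``n`` principal components of the mean-centered data."""
    X = np.asarray(X, dtype=float)
    if n > min(X.shape):
        raise ValueError(f"cannot extract {n} components from shape {X.shape}")
    return PCA(n_components=n, svd_solver="full").fit_transform(X)


def reduce_mds(D: np.ndarray, n: int) -> np.ndarray:
    """Classical (Torgerson) MDS of a distance matrix.

    Double-centers the squared distances into a Gram matrix and keeps the
    top-``n`` eigenvectors scaled by the square roots of their (clipped)
    eigenvalues.  Exact for Euclidean distance matrices of intrinsic
    dimension ≤ n.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")
    m = D.shape[0]
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:n]
    w = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(w)


def dbscan(X: np.ndarray, config: ClusterConfig) -> ClusterResult:
    """Standard DBSCAN; a point is core when its ε-ball (self included)
    holds at least ``min_points`` points."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty input")
    model = DBSCAN(eps=config.epsilon, min_samples=config.min_points,
                   metric=config.metric)
    labels = model.fit_predict(X)
    n_clusters = int(labels.max()) + 1 if (labels >= 0).any() else 0
    return ClusterResult(assignments=labels, n_clusters=n_clusters)


def _overlap_stats(result: ClusterResult, truth: np.ndarray):
    labels = result.assignments
    truth = np.asarray(truth)
    clusters = [c for c in np.unique(labels) if c != NOISE]
    per_cluster = {}
    best_sum = 0
    clustered = 0
    for c in clusters:
        mask = labels == c
        size = int(mask.sum())
        _, counts = np.unique(truth[mask], return_counts=True)
        best = int(counts.max())
        per_cluster[int(c)] = best / size
        best_sum += best
        clustered += size
    return per_cluster, best_sum, clustered


def c_precision(result: ClusterResult, truth) -> ClusterMetrics:
    """Per-cluster purity and its size-weighted / unweighted means.

    Noise points belong to no cluster and are excluded; with no clusters
    at all the precision is undefined (NaN)."""
    per_cluster, best_sum, clustered = _overlap_stats(result, truth)
    n = len(result.assignments)
    if not per_cluster:
        return ClusterMetrics(per_cluster_precision={},
                              mean_precision=float("nan"),
                              mean_precision_unweighted=float("nan"),
                              c_csi=c_csi(result, truth),
                              n_clusters=0, noise_fraction=1.0)
    weighted = best_sum / clustered
    unweighted = float(np.mean(list(per_cluster.values())))
    return ClusterMetrics(per_cluster_precision=per_cluster,
                          mean_precision=weighted,
                          mean_precision_unweighted=unweighted,
                          c_csi=c_csi(result, truth),
                          n_clusters=len(per_cluster),
                          noise_fraction=float((result.assignments == NOISE).mean()))


def c_csi(result: ClusterResult, truth) -> float:
    """Σ_i max_j |C_i∩L_j| / (Σ_i |C_i| + Σ_j |L_j| − Σ_i max_j |C_i∩L_j|).

    All labeled points enter Σ_j |L_j|, so unclustered (noise) points drag
    the score down even though they belong to no C_i."""
    truth = np.asarray(truth)
    _, best_sum, clustered = _overlap_stats(result, truth)
    total_labeled = len(truth)
    denom = clustered + total_labeled - best_sum
    return best_sum / denom if denom > 0 else 0.0


def epsilon_sweep(X: np.ndarray, truth, eps_values=None,
                  config: ClusterConfig | None = None) -> pd.DataFrame:
    """Cluster at each ε and tabulate both purity metrics.

    ``X`` is reduced once (per ``config.reduction``) before the sweep."""
    base = config or ClusterConfig()
    if eps_values is None:
        eps_values = np.geomspace(0.01, 20.0, 50)
    eps_values = np.sort(np.asarray(eps_values, dtype=float))
    if eps_values.size == 0:
        raise ValueError("empty epsilon sweep")
    X = np.asarray(X, dtype=float)
    if base.reduction == "pca":
        n = min(base.reduced_dims, min(X.shape))
        X = reduce_pca(X, n)
    elif base.reduction == "mds":
        X = reduce_mds(X, base.reduced_dims)
    rows = []
    for eps in eps_values:
        cfg = ClusterConfig(epsilon=float(eps), min_points=base.min_points,
                            metric=base.metric, reduction="none",
                            reduced_dims=base.reduced_dims)
        res = dbscan(X, cfg)
        met = c_precision(res, truth)
        rows.append({"epsilon": float(eps),
                     "mean_precision": met.mean_precision,
                     "mean_precision_unweighted": met.mean_precision_unweighted,
                     "c_csi": met.c_csi,
                     "n_clusters": res.n_clusters,
                     "noise_fraction": float((res.assignments == NOISE).mean())})
    return pd.DataFrame(rows)
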