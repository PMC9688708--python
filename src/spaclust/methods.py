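"""The six clustering methods under one hard-label contract.

k-means, hierarchical (Ward), Gaussian mixture and DBSCAN wrap
scikit-learn; k-medoids (PAM) and the 1 x k self-organizing map are
implemented here. Every method returns integer labels 0..k-1 in order
of first appearance; only DBSCAN may emit -1 for noise points, which
are excluded from cluster counts and from validity indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import DBSCAN, AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

__all__ = [
    "METHODS",
    "ClusteringResult",
    "run_method",
    "kmeans_labels",
    "dbscan_grid",
    "dbscan_sweep",
    "adjusted_rand_index",
]

METHODS = ("kmeans", "kmedoids", "hierarchical", "gmm", "som", "dbscan")


@dataclass
class ClusteringResult:
    method: str
    k_requested: int | None
    labels: np.ndarray
    seed: int
    method_params: dict = field(default_factory=dict)

    @property
    def n_clusters_found(self) -> int:
        return len(set(self.labels.tolist()) - {-1})


def _canonicalize(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance; -1 kept."""
    labels = np.asarray(labels)
    out = np.empty(len(labels), dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            out[i] = -1
        else:
            mapping.setdefault(int(lab), len(mapping))
            out[i] = mapping[int(lab)]
    return out


# ---------------------------------------------------------------------------
# k-means: k-means++ seeding, seeded restart schedule, Lloyd iterations
# run for all restarts simultaneously (the cohorts are small, so the whole
# restart batch fits in one set of vectorized updates)

def _kmeanspp_seed(X: np.ndarray, k: int, rng: np.random.Generator
                   ) -> np.ndarray:
    n = len(X)
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans_labels(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 50,
    max_iter: int = 300,
    return_trace: bool = False,
) -> np.ndarray | tuple[np.ndarray, list[float]]:
    """Best-of-``n_init`` k-means labels (smallest within-cluster sum of
    squares). With ``return_trace`` also returns the WCSS after each
    Lloyd assignment step of the winning restart, a non-increasing
    sequence by construction."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    R = n_init
    centers = np.stack([
        _kmeanspp_seed(X, k, np.random.default_rng([seed & 0x7FFFFFFF, k, r]))
        for r in range(R)
    ])  # (R, k, d)
    eye = np.eye(k)
    traces: list[list[float]] = [[] for _ in range(R)]
    labels = np.zeros((R, n), dtype=int)
    for _ in range(max_iter):
        D = ((X[None, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)
        labels = D.argmin(axis=2)  # (R, n)
        inertia = np.take_along_axis(D, labels[:, :, None], axis=2)[:, :, 0].sum(1)
        for r in range(R):
            traces[r].append(float(inertia[r]))
        onehot = eye[labels]  # (R, n, k)
        counts = onehot.sum(axis=1)  # (R, k)
        sums = np.einsum("rnk,nd->rkd", onehot, X)
        new_centers = sums / np.maximum(counts, 1.0)[:, :, None]
        empty = counts == 0
        if empty.any():  # revive an empty cluster on its restart's worst point
            for r, j in zip(*np.where(empty)):
                new_centers[r, j] = X[int(D[r].min(axis=1).argmax())]
        shift = float(((new_centers - centers) ** 2).sum())
        centers = new_centers
        if shift < 1e-24:
            break
    D = ((X[None, :, None, :] - centers[:, None, :, :]) ** 2).sum(-1)
    labels = D.argmin(axis=2)
    inertia = np.take_along_axis(D, labels[:, :, None], axis=2)[:, :, 0].sum(1)
    best = int(inertia.argmin())
    if return_trace:
        return labels[best], traces[best] + [float(inertia[best])]
    return labels[best]


# ---------------------------------------------------------------------------
# k-medoids: PAM with greedy BUILD then SWAP, Euclidean distances

def _pam(points: np.ndarray, k: int) -> np.ndarray:
    D = cdist(points, points)
    n = len(points)
    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    # SWAP until no single exchange reduces total cost
    improved = True
    while improved:
        improved = False
        cost = D[:, medoids].min(axis=1).sum()
        for mi in range(k):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                trial_cost = D[:, trial].min(axis=1).sum()
                if trial_cost < cost - 1e-12:
                    medoids, cost, improved = trial, trial_cost, True
    return np.argmin(D[:, medoids], axis=1)


# ---------------------------------------------------------------------------
# SOM: 1 x k output grid, each unit one cluster, batch-style online training

def _som_1xk(points: np.ndarray, k: int, seed: int,
             epochs: int = 200, lr0: float = 0.5) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n, d = points.shape
    # init units on distinct data points spread along the first PC
    proj = points @ np.linalg.svd(points - points.mean(0), full_matrices=False)[2][0]
    order = np.argsort(proj)
    weights = points[order[np.linspace(0, n - 1, k).astype(int)]].astype(float).copy()
    grid = np.arange(k, dtype=float)
    sigma0 = max(k / 2.0, 1e-3)
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = lr0 * (0.01 / lr0) ** frac
        sigma = sigma0 * (0.05 / sigma0) ** frac
        for i in rng.permutation(n):
            x = points[i]
            bmu = int(np.argmin(((weights - x) ** 2).sum(axis=1)))
            h = np.exp(-((grid - bmu) ** 2) / (2 * sigma ** 2))
            weights += lr * h[:, None] * (x - weights)
    return np.argmin(cdist(points, weights), axis=1)


# ---------------------------------------------------------------------------

def run_method(
    points: np.ndarray,
    method: str,
    k: int | None = None,
    seed: int = 0,
    **params,
) -> ClusteringResult:
    """Run one clustering method and return canonical hard labels.

    GMM assigns each point to its maximum-responsibility component;
    the SOM assigns each point to its best-matching unit on a 1 x k
    grid; hierarchical clustering cuts the Ward dendrogram at k.
    DBSCAN requires ``eps`` (and optional ``min_pts``) instead of k.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n = len(points)
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")

    if method == "dbscan":
        eps = params.get("eps")
        if eps is None:
            raise ValueError("dbscan requires an eps parameter")
        labels = DBSCAN(eps=eps, min_samples=params.get("min_pts", 3)).fit_predict(points)
    else:
        if k is None or not 2 <= k <= n - 1:
            raise ValueError(f"k={k} out of range [2, {n - 1}] for {method}")
        if method == "kmeans":
            labels = kmeans_labels(points, k, seed=seed,
                                   n_init=params.get("n_init", 50))
        elif method == "kmedoids":
            labels = _pam(points, k)
        elif method == "hierarchical":
            est = AgglomerativeClustering(
                n_clusters=k, linkage=params.get("linkage", "ward"))
            labels = est.fit_predict(points)
        elif method == "gmm":
            est = GaussianMixture(
                n_components=k, covariance_type="full",
                reg_covar=params.get("reg_covar", 1e-6),
                n_init=params.get("n_init", 10), random_state=seed)
            labels = est.fit_predict(points)
        elif method == "som":
            labels = _som_1xk(points, k, seed,
                              epochs=params.get("epochs", 200))

    return ClusteringResult(method=method, k_requested=k,
                            labels=_canonicalize(labels), seed=seed,
                            method_params=dict(params))


def _default_eps_grid(points: np.ndarray, n_quantiles: int = 20) -> np.ndarray:
    d = pdist(points)
    d = d[d > 0]
    if d.size == 0:
        raise ValueError("all points coincide; DBSCAN eps grid undefined")
    qs = np.linspace(0.05, 0.95, n_quantiles)
    return np.unique(np.quantile(d, qs))


def dbscan_grid(
    points: np.ndarray,
    min_pts: int = 3,
    eps_grid: np.ndarray | None = None,
) -> list[ClusteringResult]:
    """All DBSCAN runs over the epsilon grid that found >= 2 clusters
    among non-noise points. Grid defaults to 20 quantiles of the
    pairwise-distance distribution."""
    points = np.asarray(points, dtype=float)
    if eps_grid is None:
        eps_grid = _default_eps_grid(points)
    eps_grid = np.asarray(eps_grid, dtype=float)
    if eps_grid.size == 0 or np.any(np.diff(eps_grid) < 0):
        raise ValueError("eps_grid must be non-empty and ascending")
    out = []
    for eps in eps_grid:
        res = run_method(points, "dbscan", seed=0, eps=float(eps),
                         min_pts=min_pts)
        if res.n_clusters_found >= 2:
            out.append(res)
    return out


def dbscan_sweep(
    points: np.ndarray,
    min_pts: int = 3,
    eps_grid: np.ndarray | None = None,
) -> ClusteringResult:
    """Best DBSCAN run over the epsilon grid, scored by mean silhouette
    on non-noise points; runs with fewer than two clusters are skipped."""
    from .validity import silhouette_mean

    points = np.asarray(points, dtype=float)
    candidates = dbscan_grid(points, min_pts=min_pts, eps_grid=eps_grid)
    best, best_score = None, -np.inf
    for res in candidates:
        mask = res.labels >= 0
        if len(np.unique(res.labels[mask])) < 2:
            continue
        score = silhouette_mean(points[mask], res.labels[mask])
        if score > best_score:
            best, best_score = res, score
    if best is None:
        raise ValueError(
            "no eps in the grid produced >= 2 clusters; widen the grid")
    return best


def adjusted_rand_index(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Chance-adjusted partition agreement; noise points (-1 in either
    labeling) are excluded pairwise before comparison."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    keep = (a != -1) & (b != -1)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 non-noise points to compare")
    return float(adjusted_rand_score(a[keep], b[keep]))
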