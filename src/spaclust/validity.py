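"""Cluster validity criteria and optimal-k selection.

Three internal validity indices evaluate a hard partition of the PCA
score space: the mean silhouette value (cohesion vs. separation per
point), the Calinski-Harabasz index (between/within dispersion ratio,
higher is better) and the Davies-Bouldin index (worst-case spread over
separation, lower is better). All use the Euclidean metric. The optimal
cluster number is selected per criterion over k = 2..9 and reconciled
by a two-out-of-three majority vote.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "silhouette_samples",
    "silhouette_mean",
    "calinski_harabasz",
    "davies_bouldin",
    "optimal_k",
    "consensus_k",
    "fraction_above",
    "ValidityReport",
    "validity_report",
    "CRITERIA",
]

#: criterion name -> (score function, higher_is_better)
CRITERIA = {
    "silhouette": ("silhouette", True),
    "calinski_harabasz": ("calinski_harabasz", True),
    "davies_bouldin": ("davies_bouldin", False),
}

DEFAULT_K_RANGE = tuple(range(2, 10))


def _check_labels(points: np.ndarray, labels: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, list]:
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    labels = np.asarray(labels)
    if len(labels) != len(points):
        raise ValueError("labels and points length mismatch")
    uniq = list(dict.fromkeys(labels.tolist()))  # stable order
    return points, labels, uniq


def silhouette_samples(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette values s(i) = (b - a) / max(a, b).

    a(i) is the mean distance to the other members of i's cluster and
    b(i) the smallest mean distance to any other cluster. Members of
    singleton clusters get s = 0 by convention.
    """
    points, labels, uniq = _check_labels(points, labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for k=1")
    D = cdist(points, points)
    s = np.zeros(len(points))
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    for i in range(len(points)):
        own = labels[i]
        if sizes[own] == 1:
            s[i] = 0.0
            continue
        a = D[i, masks[own]].sum() / (sizes[own] - 1)
        b = min(D[i, masks[c]].mean() for c in uniq if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def silhouette_mean(points: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(silhouette_samples(points, labels)))


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """Variance-ratio criterion (B/(k-1)) / (W/(n-k)).

    Zero within-cluster scatter (every cluster collapsed onto its
    centroid) is reported as +inf — perfect separation — rather than an
    error, so sweeps over degenerate fixtures do not abort.
    """
    points, labels, uniq = _check_labels(points, labels)
    n, k = len(points), len(uniq)
    if not 2 <= k < n:
        raise ValueError("Calinski-Harabasz requires 2 <= k < n")
    grand = points.mean(axis=0)
    B = W = 0.0
    for c in uniq:
        cluster = points[labels == c]
        centroid = cluster.mean(axis=0)
        B += len(cluster) * float(np.sum((centroid - grand) ** 2))
        W += float(np.sum((cluster - centroid) ** 2))
    if W == 0:
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def davies_bouldin(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean over clusters of the worst (S_i + S_j) / M_ij ratio, where
    S is the mean distance to the own centroid and M the centroid
    distance. Coincident centroids make the ratio undefined."""
    points, labels, uniq = _check_labels(points, labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("Davies-Bouldin requires k >= 2")
    centroids = np.array([points[labels == c].mean(axis=0) for c in uniq])
    spreads = np.array([
        float(cdist(points[labels == c], centroids[i:i + 1]).mean())
        for i, c in enumerate(uniq)
    ])
    M = cdist(centroids, centroids)
    if np.any(M[~np.eye(k, dtype=bool)] == 0):
        raise ValueError("Davies-Bouldin undefined for coincident centroids")
    db = 0.0
    for i in range(k):
        ratios = [(spreads[i] + spreads[j]) / M[i, j] for j in range(k) if j != i]
        db += max(ratios)
    return db / k


def criterion_score(name: str, points: np.ndarray, labels: np.ndarray) -> float:
    fn = {"silhouette": silhouette_mean,
          "calinski_harabasz": calinski_harabasz,
          "davies_bouldin": davies_bouldin}[name]
    return fn(points, labels)


def _argbest(scores_by_k: dict[int, float], higher_is_better: bool) -> int:
    """Best k under a criterion; ties break toward smaller k (parsimony)."""
    best_k, best = None, None
    for k in sorted(scores_by_k):
        v = scores_by_k[k]
        if not np.isfinite(v) and not (higher_is_better and v == math.inf):
            continue
        if best is None or (v > best if higher_is_better else v < best):
            best_k, best = k, v
    if best_k is None:
        raise ValueError("no valid k in sweep")
    return best_k


def optimal_k(
    points: np.ndarray,
    method: str,
    criterion: str,
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
    method_params: dict | None = None,
) -> int:
    """Run a clustering method over ``k_range`` and return the k that
    optimizes ``criterion`` (argmax for silhouette/CH, argmin for DB)."""
    from . import methods as _methods

    points = np.asarray(points, dtype=float)
    if len(points) <= max(k_range):
        raise ValueError("need more points than the largest k")
    _, higher = CRITERIA[criterion]
    scores: dict[int, float] = {}
    for k in k_range:
        try:
            res = _methods.run_method(points, method, k, seed=seed,
                                      **(method_params or {}))
            scores[k] = criterion_score(criterion, points, res.labels)
        except Exception as exc:  # degenerate k: skip with warning
            warnings.warn(f"{method} failed at k={k}: {exc}")
    if not scores:
        raise ValueError(f"{method} failed at every k in {k_range}")
    return _argbest(scores, higher)


def consensus_k(votes: dict[str, int]) -> int:
    """Two-out-of-three majority over the criteria's optimal k; with no
    majority the silhouette criterion decides (the combination search
    itself is silhouette-driven)."""
    if set(votes) != set(CRITERIA):
        raise ValueError(f"expected one vote per criterion, got {sorted(votes)}")
    values = list(votes.values())
    for v in values:
        if values.count(v) >= 2:
            return v
    return votes["silhouette"]


def fraction_above(values: np.ndarray, threshold: float = 0.6) -> float:
    """Proportion of per-sample values strictly greater than threshold."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty value set")
    return float(np.mean(values > threshold))


@dataclass
class ValidityReport:
    """Per-method validity sweep: index values per k, the optimal k under
    each criterion, the majority-vote consensus, and per-subject
    silhouettes at the consensus partition.

    Conventions recorded for auditability: Euclidean metric; singleton
    clusters contribute silhouette 0.
    """

    method: str
    condition: str
    per_k: dict[int, dict[str, float]]
    optimal_k_per_criterion: dict[str, int]
    consensus_k: int
    per_sample_silhouette_at_consensus: np.ndarray
    labels_at_consensus: np.ndarray
    metric: str = "euclidean"
    singleton_silhouette: float = 0.0


def _score_partition(points: np.ndarray, labels: np.ndarray
                     ) -> dict[str, float] | None:
    mask = labels >= 0  # DBSCAN noise excluded from index computation
    pts, lab = points[mask], labels[mask]
    if len(np.unique(lab)) < 2 or len(pts) <= len(np.unique(lab)):
        return None
    out = {"silhouette": silhouette_mean(pts, lab),
           "calinski_harabasz": calinski_harabasz(pts, lab)}
    try:
        out["davies_bouldin"] = davies_bouldin(pts, lab)
    except ValueError:
        out["davies_bouldin"] = math.nan
    return out


def validity_report(
    points: np.ndarray,
    method: str,
    condition: str = "",
    k_range: tuple[int, ...] = DEFAULT_K_RANGE,
    seed: int = 0,
    method_params: dict | None = None,
) -> ValidityReport:
    """Full three-criterion sweep for one clustering method.

    k-requiring methods are run at each k in range. DBSCAN has no k
    parameter: its epsilon grid is swept instead and each run enters the
    table under the cluster count it found, so the criteria effectively
    vote over densities.
    """
    from . import methods as _methods

    points = np.asarray(points, dtype=float)
    params = dict(method_params or {})
    partitions: dict[int, list[np.ndarray]] = {}

    if method == "dbscan":
        results = _methods.dbscan_grid(points, **params)
        for res in results:
            partitions.setdefault(res.n_clusters_found, []).append(res.labels)
    else:
        for k in k_range:
            try:
                res = _methods.run_method(points, method, k, seed=seed, **params)
            except Exception as exc:
                warnings.warn(f"{method} failed at k={k}: {exc}")
                continue
            partitions.setdefault(k, []).append(res.labels)

    per_k: dict[int, dict[str, float]] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k, label_sets in sorted(partitions.items()):
        scored = [(labels, _score_partition(points, labels))
                  for labels in label_sets]
        scored = [(l, s) for l, s in scored if s is not None]
        if not scored:
            continue
        labels, score = max(scored, key=lambda ls: ls[1]["silhouette"])
        per_k[k] = score
        best_labels[k] = labels
    if not per_k:
        raise ValueError(f"{method}: no partition with >= 2 clusters found")

    optimal = {}
    for crit, (_, higher) in CRITERIA.items():
        valid = {k: v[crit] for k, v in per_k.items() if not math.isnan(v[crit])}
        optimal[crit] = _argbest(valid, higher)
    consensus = consensus_k(optimal)

    labels_cons = best_labels[consensus]
    mask = labels_cons >= 0
    sil = np.full(len(points), np.nan)
    sil[mask] = silhouette_samples(points[mask], labels_cons[mask])
    return ValidityReport(
        method=method, condition=condition, per_k=per_k,
        optimal_k_per_criterion=optimal, consensus_k=consensus,
        per_sample_silhouette_at_consensus=sil,
        labels_at_consensus=labels_cons,
    )
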