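"""Exhaustive constrained 5-feature combination search.

Candidate feature sets take one parameter from the prefrontal-cortex
pool, one from the visual-cortex pool and three from the systemic
pool (4 x 4 x C(6,3) = 320 subsets by default). Each subset is scored
per condition by the best mean silhouette that k-means achieves over
k = 2..9 on the subset's PCA scores; subsets exceeding the silhouette
threshold in *every* condition are ranked to give the best common
combinations.

Task performance is excluded from the default pools: behaviourally the
cohort is near-homogeneous, so the word count carries little clustering
signal, and structurally it is not a systemic-physiology parameter. It
can be appended to a pool via configuration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, product

from .records import PFC_PARAMS, SYSTEMIC_PARAMS, VC_PARAMS, FeatureTable
from .reduction import pca_project
from .validity import silhouette_mean, _argbest

__all__ = [
    "FeaturePools",
    "CombinationScore",
    "enumerate_combinations",
    "score_combination",
    "search_combinations",
    "select_common_combinations",
]


@dataclass(frozen=True)
class FeaturePools:
    pfc_pool: tuple[str, ...] = PFC_PARAMS
    vc_pool: tuple[str, ...] = VC_PARAMS
    systemic_pool: tuple[str, ...] = SYSTEMIC_PARAMS

    def __post_init__(self) -> None:
        pools = (self.pfc_pool, self.vc_pool, self.systemic_pool)
        names = [n for pool in pools for n in pool]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"pools must be disjoint; duplicated: {dup}")
        if len(self.systemic_pool) < 3:
            raise ValueError("systemic pool must contain >= 3 features")
        if not self.pfc_pool or not self.vc_pool:
            raise ValueError("PFC and VC pools must be non-empty")


def enumerate_combinations(pools: FeaturePools) -> list[tuple[str, ...]]:
    """All (1 PFC, 1 VC, 3 systemic) subsets in lexicographic pool order."""
    return [
        (pfc, vc) + trio
        for pfc, vc, trio in product(pools.pfc_pool, pools.vc_pool,
                                     combinations(pools.systemic_pool, 3))
    ]


@dataclass
class CombinationScore:
    features: tuple[str, ...]
    per_condition: dict[str, tuple[float, int]]  # cond -> (best_sil, best_k)
    failed: bool = False

    def passes_threshold(self, threshold: float = 0.6) -> bool:
        if self.failed:
            return False
        return all(sil > threshold for sil, _ in self.per_condition.values())

    @property
    def rank_score(self) -> float:
        if self.failed:
            return -math.inf
        return float(sum(s for s, _ in self.per_condition.values())
                     / len(self.per_condition))


def _best_silhouette_over_k(
    points, k_range: tuple[int, ...], seed: int, n_init: int
) -> tuple[float, int]:
    from .methods import run_method

    scores: dict[int, float] = {}
    for k in k_range:
        if k > len(points) - 1:
            continue
        res = run_method(points, "kmeans", k, seed=seed, n_init=n_init)
        if res.n_clusters_found < 2:
            continue
        scores[k] = silhouette_mean(points, res.labels)
    if not scores:
        raise ValueError("no k produced a scoreable partition")
    best_k = _argbest(scores, higher_is_better=True)
    return scores[best_k], best_k


def score_combination(
    tables: dict[str, FeatureTable],
    combo: tuple[str, ...],
    k_range: tuple[int, ...] = tuple(range(2, 10)),
    seed: int = 0,
    variance_threshold: float = 0.8,
    n_init: int = 10,
) -> CombinationScore:
    """Per-condition best silhouette (and its k) for one feature subset.

    The subset columns are PCA-projected at the variance threshold and
    clustered with k-means at each k; the subset's condition score is
    the maximum mean silhouette over k, ties toward smaller k. Subsets
    degenerate in any condition (e.g. all-constant columns) are marked
    failed and drop out of the ranking.
    """
    per_condition: dict[str, tuple[float, int]] = {}
    for cond, table in tables.items():
        if table.provenance != "normalized":
            raise ValueError("score_combination expects normalized tables")
        sub = table.subset(combo)
        try:
            projected = pca_project(sub, variance_threshold)
            sil, k = _best_silhouette_over_k(projected.scores, k_range,
                                             seed, n_init)
        except ValueError as exc:
            warnings.warn(f"combination {combo} failed in {cond}: {exc}")
            return CombinationScore(combo, {}, failed=True)
        per_condition[cond] = (sil, k)
    return CombinationScore(combo, per_condition)


def search_combinations(
    tables: dict[str, FeatureTable],
    pools: FeaturePools | None = None,
    k_range: tuple[int, ...] = tuple(range(2, 10)),
    seed: int = 0,
    variance_threshold: float = 0.8,
    n_init: int = 10,
) -> list[CombinationScore]:
    """Score every constrained combination on every condition."""
    pools = pools or FeaturePools()
    return [
        score_combination(tables, combo, k_range, seed, variance_threshold,
                          n_init)
        for combo in enumerate_combinations(pools)
    ]


def select_common_combinations(
    scores: list[CombinationScore],
    threshold: float = 0.6,
    top_n: int = 5,
) -> list[CombinationScore]:
    """Combinations whose best silhouette exceeds the threshold in every
    condition, ranked by the mean of per-condition best silhouettes."""
    if not scores:
        raise ValueError("no combination scores supplied")
    passing = [s for s in scores if s.passes_threshold(threshold)]
    if not passing:
        warnings.warn(
            f"no combination exceeded silhouette {threshold} in all conditions")
        return []
    passing.sort(key=lambda s: (-s.rank_score, s.features))
    return passing[:top_n]
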