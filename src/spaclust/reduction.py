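"""Min-max normalization and variance-thresholded PCA.

Features live on very different scales (µM-seconds for hemoglobin AUCs,
µS-seconds for skin conductance, a raw word count for performance), so
each column is mapped onto [0, 1] before clustering. PCA then retains
the smallest number of components whose cumulative explained variance
reaches the threshold (80% by default), which on 5-feature subsets
typically keeps two components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .records import FeatureTable

__all__ = ["min_max_normalize", "pca_project", "ProjectedData"]

logger = logging.getLogger(__name__)


def min_max_normalize(table: FeatureTable) -> FeatureTable:
    """Map each feature column onto [0, 1] by (x - min) / (max - min).

    A degenerate (constant) column carries no between-subject
    information; it is mapped to all zeros with a warning instead of
    erroring, so exhaustive combination sweeps stay total.
    """
    if len(table.data) < 2:
        raise ValueError("normalization needs at least 2 subjects")
    out = {}
    for col in table.data.columns:
        x = table.data[col].to_numpy(dtype=float)
        span = np.ptp(x)
        if span == 0:
            logger.warning("constant feature column %r normalized to 0", col)
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - x.min()) / span
    frame = pd.DataFrame(out, index=table.data.index)
    return FeatureTable(table.condition, frame, provenance="normalized")


@dataclass
class ProjectedData:
    """PCA scores retained under the explained-variance threshold.

    ``explained_variance_ratio`` covers *all* components (it sums to 1
    at full rank); ``scores`` and ``component_loadings`` cover only the
    ``n_components`` retained ones.
    """

    scores: np.ndarray                      # subjects x n_components
    explained_variance_ratio: np.ndarray    # all components
    n_components: int
    component_loadings: np.ndarray          # features x n_components
    centering_means: np.ndarray             # per feature
    feature_names: list[str]
    subject_ids: list[str]

    def reconstruct(self) -> np.ndarray:
        """Inverse transform; exact when all components are retained."""
        return self.scores @ self.component_loadings.T + self.centering_means


def pca_project(table: FeatureTable, variance_threshold: float = 0.8
                ) -> ProjectedData:
    """Project a feature table onto its leading principal components.

    Columns are mean-centered but not re-standardized (min-max scaling
    is the designated scaling step); retained dimensionality is the
    smallest m whose cumulative explained-variance ratio reaches
    ``variance_threshold``. Loading signs are fixed so each component's
    largest-magnitude loading is positive, making score plots
    reproducible across runs and backends.
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise ValueError("variance_threshold must be in (0, 1]")
    X = table.values
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("PCA needs >= 2 subjects and >= 1 feature")

    pca = PCA(n_components=None, svd_solver="full")
    scores_full = pca.fit_transform(X)
    ratios = pca.explained_variance_ratio_.copy()
    if not np.all(np.isfinite(ratios)):  # zero-variance input
        ratios = np.zeros_like(ratios)
        ratios[0] = 1.0

    cum = np.cumsum(ratios)
    n_comp = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    n_comp = min(n_comp, len(ratios))

    loadings = pca.components_.T.copy()  # features x components
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0),
                            np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    scores_full = scores_full * flip

    return ProjectedData(
        scores=scores_full[:, :n_comp],
        explained_variance_ratio=ratios,
        n_components=n_comp,
        component_loadings=loadings[:, :n_comp],
        centering_means=pca.mean_.copy(),
        feature_names=table.feature_names,
        subject_ids=table.subject_ids,
    )
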