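"""Task-phase AUC feature extraction and feature correlations.

Each physiological channel is reduced to a single scalar per subject
and condition: the trapezoidal integral of the baseline-referenced
signal over the task phase. Together with the task-performance word
count this yields the 15-feature table fed to normalization, PCA and
clustering.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .records import (
    ALL_FEATURES,
    TASK_PERFORMANCE,
    TIMESERIES_PARAMS,
    FeatureTable,
    TimeSeriesRecord,
)

__all__ = [
    "baseline_level",
    "auc_task_phase",
    "extract_subject_features",
    "build_feature_table",
    "pearson_correlation",
    "correlation_table",
]

DEFAULT_BASELINE_WINDOW = 120.0  # steady-state window at the end of baseline


def baseline_level(record: TimeSeriesRecord, window: float = DEFAULT_BASELINE_WINDOW
                   ) -> float:
    """Mean signal over the last ``window`` seconds of the baseline phase."""
    b0, t1, _, _ = record.phase_bounds
    if window <= 0:
        raise ValueError("baseline window must be positive")
    if window > t1 - b0 + 1e-9:
        raise ValueError(
            f"baseline window {window}s exceeds baseline duration {t1 - b0}s"
        )
    _, samples = record.window(t1 - window, t1)
    if samples.size == 0:
        raise ValueError("baseline window contains no samples")
    return float(np.mean(samples))


def auc_task_phase(record: TimeSeriesRecord, baseline: float) -> float:
    """Trapezoidal integral of (signal - baseline) over the task phase.

    Sign-preserving: deflections below the baseline reference contribute
    negatively, so the AUC feature encodes the direction of the response.
    """
    _, t1, t2, _ = record.phase_bounds
    t, samples = record.window(t1, t2)
    if samples.size < 2:
        raise ValueError("task phase must contain at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError(
            f"non-finite samples in task phase of "
            f"{record.subject_id}/{record.parameter}"
        )
    return float(np.trapezoid(samples - baseline, t))


def extract_subject_features(
    records: Iterable[TimeSeriesRecord],
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    subtract_baseline: bool = True,
) -> dict[str, float]:
    """AUC features for one subject's channel set, keyed by parameter."""
    feats: dict[str, float] = {}
    for rec in records:
        ref = baseline_level(rec, baseline_window) if subtract_baseline else 0.0
        feats[rec.parameter] = auc_task_phase(rec, ref)
    return feats


def build_feature_table(
    records_by_subject: Mapping[str, Iterable[TimeSeriesRecord]],
    task_performance: Mapping[str, float],
    condition: str,
    baseline_window: float = DEFAULT_BASELINE_WINDOW,
    subtract_baseline: bool = True,
) -> FeatureTable:
    """Assemble the subjects x 15 feature table for one condition.

    Every subject must provide all 14 channels and a task-performance
    value; incomplete subjects raise with the offending (subject,
    parameter) pairs listed rather than being silently dropped.
    """
    rows = {}
    missing: list[tuple[str, str]] = []
    for sid in sorted(records_by_subject):
        feats = extract_subject_features(records_by_subject[sid],
                                         baseline_window, subtract_baseline)
        absent = [p for p in TIMESERIES_PARAMS if p not in feats]
        if absent:
            missing.extend((sid, p) for p in absent)
            continue
        if sid not in task_performance:
            missing.append((sid, TASK_PERFORMANCE))
            continue
        row = [feats[p] for p in TIMESERIES_PARAMS]
        row.append(float(task_performance[sid]))
        rows[sid] = row
    if missing:
        raise ValueError(f"missing channels: {missing}")
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(ALL_FEATURES))
    return FeatureTable(condition, frame, provenance="raw_auc")


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; errors on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def correlation_table(
    table: FeatureTable,
    cerebrovascular: Iterable[str],
    systemic: Iterable[str],
) -> pd.DataFrame:
    """Pairwise Pearson r (and p) between cerebrovascular and systemic
    features — the cross-domain coupling summary reported alongside the
    clustering."""
    rows = []
    for cf in cerebrovascular:
        for sf in systemic:
            res = stats.pearsonr(table.data[cf], table.data[sf])
            rows.append({
                "condition": table.condition,
                "cerebrovascular": cf,
                "systemic": sf,
                "r": float(res.statistic),
                "p": float(res.pvalue),
            })
    return pd.DataFrame(rows)
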