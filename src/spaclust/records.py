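"""Core data containers: phase-annotated physiological time series and
subject x feature tables.

The parameter vocabulary covers the 14 time-varying signals recorded
concurrently during a colored-light verbal-fluency protocol — cerebral
hemodynamics at two sites (prefrontal cortex, PFC; visual cortex, VC)
plus systemic physiology — and one scalar behavioural measure
(task performance, a word count).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: fNIRS-derived parameters at the prefrontal cortex (µM except StO2 in %)
PFC_PARAMS: tuple[str, ...] = ("O2Hb-PFC", "HHb-PFC", "tHb-PFC", "StO2-PFC")
#: fNIRS-derived parameters at the visual cortex
VC_PARAMS: tuple[str, ...] = ("O2Hb-VC", "HHb-VC", "tHb-VC", "StO2-VC")
#: systemic physiology: heart rate (bpm), mean arterial pressure (mmHg),
#: arterial O2 saturation (%), respiration rate (breaths/min),
#: end-tidal CO2 partial pressure (mmHg), skin conductance (µS)
SYSTEMIC_PARAMS: tuple[str, ...] = ("HR", "MAP", "SpO2", "RR", "PETCO2", "SC")

#: the 14 time-varying channels
TIMESERIES_PARAMS: tuple[str, ...] = PFC_PARAMS + VC_PARAMS + SYSTEMIC_PARAMS

TASK_PERFORMANCE: str = "task_performance"

#: the full 15-feature vocabulary (14 task-phase AUC features + performance)
ALL_FEATURES: tuple[str, ...] = TIMESERIES_PARAMS + (TASK_PERFORMANCE,)


@dataclass
class TimeSeriesRecord:
    """One named physiological channel for one subject and condition.

    ``phase_bounds`` is ``(baseline_start, task_start, task_end,
    recovery_end)`` in seconds; samples are uniformly spaced at
    ``sampling_rate`` starting at ``baseline_start``.
    """

    subject_id: str
    condition: str
    parameter: str
    sampling_rate: float
    samples: np.ndarray
    phase_bounds: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if self.parameter not in TIMESERIES_PARAMS:
            raise ValueError(
                f"unknown parameter {self.parameter!r}; expected one of "
                f"{TIMESERIES_PARAMS}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        b = self.phase_bounds
        if not (b[0] < b[1] < b[2] < b[3]):
            raise ValueError(f"phase bounds must be strictly increasing, got {b}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        span = b[0] + (len(self.samples) - 1) / self.sampling_rate
        if span < b[3] - 1e-9:
            raise ValueError(
                f"samples span {span:.1f}s but recovery ends at {b[3]:.1f}s"
            )

    @property
    def times(self) -> np.ndarray:
        return self.phase_bounds[0] + np.arange(len(self.samples)) / self.sampling_rate

    def window(self, t_start: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        """Samples with timestamps in the closed interval [t_start, t_end]."""
        t = self.times
        mask = (t >= t_start - 1e-9) & (t <= t_end + 1e-9)
        return t[mask], self.samples[mask]


@dataclass
class FeatureTable:
    """Subjects x features matrix for one experimental condition.

    ``data`` is indexed by subject id with one column per feature name;
    ``provenance`` is ``"raw_auc"`` for freshly extracted tables and
    ``"normalized"`` after min-max scaling.
    """

    condition: str
    data: pd.DataFrame
    provenance: str = "raw_auc"

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"feature table contains missing entries in {bad}")
        if self.data.columns.duplicated().any():
            raise ValueError("feature names must be unique")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.data.columns]
        if missing:
            raise KeyError(f"features not in table: {missing}")
        return FeatureTable(self.condition, self.data[list(features)].copy(),
                            self.provenance)
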