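"""Synthetic two-condition cohorts with planted reactivity groups.

No raw recordings from the original study are publicly deposited, so
every downstream stage is exercised on simulated cohorts that emulate
the study conditions: 30 subjects measured under blue and red colored
light, 14 physiological channels sampled through an 8-min baseline /
9-min task / 15-min recovery protocol, plus one task-performance scalar.
Group structure is planted as group-specific task-phase response
amplitudes; subjects within a group share a mean amplitude and differ
by a between-subject jitter, on top of sample noise and slow drift.

Two generation modes share the same mixture parameterisation:

* :func:`generate_cohort` produces full time series, to be fed through
  feature extraction;
* :func:`generate_feature_table` draws task-phase AUC features directly
  from the implied Gaussian mixture (component means = amplitude x task
  duration), for fast downstream testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .records import (  # noqa
    ALL_FEATURES,
    TASK_PERFORMANCE,
    TIMESERIES_PARAMS,
    FeatureTable,
    TimeSeriesRecord,
)

__all__ = [
    "ProtocolSpec",
    "GroupTemplate",
    "CohortSpec",
    "ConditionData",
    "CohortData",
    "generate_subject",
    "generate_cohort",
    "generate_feature_table",
    "default_templates",
    "default_cohort_spec",
    "scale_template_contrast",
    "component_separation_sd",
    "BASELINE_LEVELS",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """Phase durations (s) and sampling rate (Hz) of the recording protocol."""

    baseline_duration: float = 480.0
    task_duration: float = 540.0
    recovery_duration: float = 900.0
    sampling_rate: float = 1.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "task_duration", "recovery_duration",
                     "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def phase_bounds(self) -> tuple[float, float, float, float]:
        b = self.baseline_duration
        t = b + self.task_duration
        return (0.0, b, t, t + self.recovery_duration)

    @property
    def total_duration(self) -> float:
        return self.phase_bounds[3]


# resting-state operating points the task responses ride on, in each
# parameter's native unit (µM, %, bpm, mmHg, breaths/min, µS)
BASELINE_LEVELS: dict[str, float] = {
    "O2Hb-PFC": 28.0, "HHb-PFC": 12.0, "tHb-PFC": 40.0, "StO2-PFC": 68.0,
    "O2Hb-VC": 26.0, "HHb-VC": 13.0, "tHb-VC": 39.0, "StO2-VC": 66.0,
    "HR": 70.0, "MAP": 85.0, "SpO2": 98.0, "RR": 15.0, "PETCO2": 38.0,
    "SC": 5.0,
}

# between-subject spread of the task response within a reactivity group.
# The model draws this jitter independently per channel, whereas in real
# cohorts within-group variation is strongly correlated across channels;
# the SDs are therefore set below the per-channel ranges quoted for the
# observed groups so that the *joint* five-feature separation lands in
# the clustering regime the study reports (mean silhouette ~0.7-0.9,
# most subjects above 0.6).
_AMPLITUDE_SD: dict[str, float] = {
    "O2Hb-PFC": 0.25, "HHb-PFC": 0.12, "tHb-PFC": 0.3, "StO2-PFC": 0.25,
    "O2Hb-VC": 0.25, "HHb-VC": 0.12, "tHb-VC": 0.3, "StO2-VC": 0.25,
    "HR": 0.8, "MAP": 0.8, "SpO2": 0.1, "RR": 0.4, "PETCO2": 0.4, "SC": 0.2,
}

# per-sample measurement noise at 1 Hz
_NOISE_SD: dict[str, float] = {
    "O2Hb-PFC": 0.3, "HHb-PFC": 0.2, "tHb-PFC": 0.4, "StO2-PFC": 0.5,
    "O2Hb-VC": 0.3, "HHb-VC": 0.2, "tHb-VC": 0.4, "StO2-VC": 0.5,
    "HR": 2.0, "MAP": 2.0, "SpO2": 0.3, "RR": 1.0, "PETCO2": 1.0, "SC": 0.2,
}

# slow instrumental/physiological drift, unit per minute
_DRIFT_SD: dict[str, float] = {
    "O2Hb-PFC": 0.05, "HHb-PFC": 0.03, "tHb-PFC": 0.06, "StO2-PFC": 0.05,
    "O2Hb-VC": 0.05, "HHb-VC": 0.03, "tHb-VC": 0.06, "StO2-VC": 0.05,
    "HR": 0.2, "MAP": 0.2, "SpO2": 0.02, "RR": 0.1, "PETCO2": 0.1, "SC": 0.05,
}

# group-mean task-phase response amplitudes; SC and O2Hb-VC anchors follow
# the ranges quoted for the extreme groups (ΔSC ~1 µS vs >11 µS)
_BLUE_AMPLITUDES: dict[str, tuple[float, ...]] = {
    "O2Hb-PFC": (2.0, 0.5, -1.0), "HHb-PFC": (-1.0, 0.3, -0.2),
    "tHb-PFC": (1.5, 0.8, -1.2), "StO2-PFC": (1.5, 0.0, -1.0),
    "O2Hb-VC": (1.28, -0.5, 0.55), "HHb-VC": (-0.4, 0.5, 0.0),
    "tHb-VC": (1.0, 0.0, 0.6), "StO2-VC": (1.0, -0.8, 0.3),
    "HR": (5.0, 1.0, 8.0), "MAP": (4.0, 1.0, 7.0), "SpO2": (-0.5, 0.3, -1.2),
    "RR": (2.0, 0.5, 3.5), "PETCO2": (-2.0, -0.5, -4.0),
    "SC": (1.1, 4.5, 11.4),
}

# The five red-light groups are parameterized by two latent reactivity
# axes — u, a sympathetic-arousal axis that drives SC, HR, MAP and the
# hypocapnia-linked responses, and v, an orthogonal cerebral-hemodynamic
# axis. Group mean patterns therefore span a plane: the five phenotypes
# stay mutually separated in the leading two principal components of any
# informative feature subset, as observed for the real cohort. Vertices
# approximate a regular pentagon in (u, v).
_RED_LATENT: tuple[tuple[float, float], ...] = (
    (0.02, 0.15),   # group 1: low arousal (ΔSC ~ 1 µS, O2Hb-VC positive)
    (0.50, 0.50),
    (0.98, 0.15),   # group 3: high arousal (ΔSC > 11 µS, O2Hb-VC negative)
    (0.79, -0.40),
    (0.21, -0.40),
)

# parameter -> (base, u loading, v loading), native units; loadings are
# balanced between the axes so neither latent direction dominates total
# variance (the observed cohort needed two principal components)
_RED_LOADINGS: dict[str, tuple[float, float, float]] = {
    "O2Hb-PFC": (0.0, 1.3, 3.5), "HHb-PFC": (-1.2, 1.3, 2.2),
    "tHb-PFC": (0.2, 1.0, 3.2), "StO2-PFC": (-0.5, 1.0, 3.5),
    "O2Hb-VC": (0.7, -1.9, 1.6), "HHb-VC": (0.4, -0.6, -1.4),
    "tHb-VC": (0.6, -0.6, 2.2), "StO2-VC": (0.9, -1.6, 2.9),
    "HR": (1.0, 12.8, 4.8), "MAP": (0.5, 11.2, 4.8),
    "SpO2": (-0.5, 0.3, 2.2), "RR": (0.3, 4.0, 3.2),
    "PETCO2": (-0.3, -5.6, -3.2), "SC": (0.5, 17.5, 0.0),
}

_RED_AMPLITUDES: dict[str, tuple[float, ...]] = {
    p: tuple(round(base + bu * u + bv * v, 3)
             for (u, v) in _RED_LATENT)
    for p, (base, bu, bv) in _RED_LOADINGS.items()
}


@dataclass(frozen=True)
class GroupTemplate:
    """Reactivity pattern of one planted subject group.

    ``response_amplitude`` maps every time-varying parameter to the
    group-mean task response in the parameter's native unit;
    ``amplitude_sd`` is the between-subject spread of that response
    within the group; ``noise_sd`` is per-sample measurement noise and
    ``drift_sd`` the SD of a random linear drift (unit per minute).
    """

    group_id: str
    response_amplitude: dict[str, float]
    amplitude_sd: dict[str, float] = field(default_factory=lambda: dict(_AMPLITUDE_SD))
    onset_time_constant: float = 30.0
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_NOISE_SD))
    drift_sd: dict[str, float] = field(default_factory=lambda: dict(_DRIFT_SD))

    def __post_init__(self) -> None:
        missing = [p for p in TIMESERIES_PARAMS if p not in self.response_amplitude]
        if missing:
            raise ValueError(
                f"template {self.group_id!r} missing amplitudes for {missing}"
            )
        if self.onset_time_constant <= 0:
            raise ValueError("onset_time_constant must be positive")
        for name in ("amplitude_sd", "noise_sd", "drift_sd"):
            vals = getattr(self, name)
            if any(v < 0 for v in vals.values()):
                raise ValueError(f"{name} entries must be non-negative")

    def sd_for(self, parameter: str) -> float:
        return self.amplitude_sd.get(parameter, 0.0)


def default_templates(condition: str) -> list[GroupTemplate]:
    """The planted group templates: 3 groups under blue, 5 under red light."""
    table = {"blue": _BLUE_AMPLITUDES, "red": _RED_AMPLITUDES}[condition]
    n_groups = len(next(iter(table.values())))
    return [
        GroupTemplate(
            group_id=f"{condition}-g{g + 1}",
            response_amplitude={p: table[p][g] for p in TIMESERIES_PARAMS},
        )
        for g in range(n_groups)
    ]


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic two-condition cohort."""

    n_subjects: int = 30
    conditions: tuple[str, ...] = ("blue", "red")
    templates_per_condition: dict[str, list[GroupTemplate]] = field(
        default_factory=lambda: {c: default_templates(c) for c in ("blue", "red")}
    )
    group_proportions_per_condition: dict[str, tuple[float, ...]] | None = None
    task_performance_mean: float = 58.0
    task_performance_sd: float = 12.0
    seed: int = 0
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for cond in self.conditions:
            if cond not in self.templates_per_condition:
                raise ValueError(f"no templates for condition {cond!r}")
            templates = self.templates_per_condition[cond]
            if len(templates) < 1:
                raise ValueError(f"condition {cond!r} needs >= 1 template")
            if self.n_subjects < len(templates):
                raise ValueError(
                    f"n_subjects={self.n_subjects} cannot realize "
                    f"{len(templates)} groups in condition {cond!r}"
                )
            props = self.proportions(cond)
            if len(props) != len(templates):
                raise ValueError(
                    f"condition {cond!r}: {len(props)} proportions for "
                    f"{len(templates)} templates"
                )
            if any(p < 0 for p in props) or not math.isclose(sum(props), 1.0,
                                                             abs_tol=1e-9):
                raise ValueError(f"proportions for {cond!r} must sum to 1")

    def proportions(self, condition: str) -> tuple[float, ...]:
        if self.group_proportions_per_condition is not None:
            return tuple(self.group_proportions_per_condition[condition])
        n = len(self.templates_per_condition[condition])
        return tuple(1.0 / n for _ in range(n))


def default_cohort_spec(seed: int = 0, separation: float = 1.0,
                        n_subjects: int = 30) -> CohortSpec:
    """The study-condition cohort: 30 subjects, 3 blue / 5 red groups.

    ``separation`` rescales the between-group amplitude contrast around
    the across-group mean (1.0 = the default templates; 0 = no group
    structure).
    """
    templates = {
        cond: scale_template_contrast(default_templates(cond), separation)
        for cond in ("blue", "red")
    }
    return CohortSpec(n_subjects=n_subjects, seed=seed,
                      templates_per_condition=templates)


def informative_only_templates(templates: list[GroupTemplate],
                               features: tuple[str, ...]
                               ) -> list[GroupTemplate]:
    """Remove between-group contrast from every parameter not listed.

    The returned templates plant group structure exclusively through
    ``features``; all other parameters keep their within-group
    variability but share one across-group mean amplitude, making them
    pure nuisance dimensions for feature-selection benchmarks.
    """
    means = {
        p: float(np.mean([t.response_amplitude[p] for t in templates]))
        for p in TIMESERIES_PARAMS
    }
    return [
        replace(t, response_amplitude={
            p: (t.response_amplitude[p] if p in features else means[p])
            for p in TIMESERIES_PARAMS
        })
        for t in templates
    ]


def scale_template_contrast(templates: list[GroupTemplate],
                            separation: float) -> list[GroupTemplate]:
    """Scale between-group amplitude differences by ``separation``.

    Each group's amplitude is moved toward (separation < 1) or away from
    (separation > 1) the across-group mean; within-group variability and
    noise are untouched, so ``separation`` controls effect size in the
    planted-partition sense.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    means = {
        p: float(np.mean([t.response_amplitude[p] for t in templates]))
        for p in TIMESERIES_PARAMS
    }
    return [
        replace(t, response_amplitude={
            p: means[p] + separation * (t.response_amplitude[p] - means[p])
            for p in TIMESERIES_PARAMS
        })
        for t in templates
    ]


# ---------------------------------------------------------------------------
# generation

def _subject_rng(seed: int, condition_index: int, subject_index: int,
                 stream: int = 0) -> np.random.Generator:
    # keyed substreams: adding subjects or conditions never reshuffles
    # the draws of earlier subjects
    return np.random.default_rng([seed & 0x7FFFFFFF, condition_index,
                                  subject_index, stream])


def _response_curve(protocol: ProtocolSpec, tau: float) -> np.ndarray:
    """Unit-amplitude task response: saturating onset during the task
    phase, exponential return toward baseline during recovery."""
    b0, t1, t2, t3 = protocol.phase_bounds
    n = int(round(protocol.total_duration * protocol.sampling_rate)) + 1
    t = np.arange(n) / protocol.sampling_rate
    r = np.zeros(n)
    task = (t >= t1) & (t <= t2)
    r[task] = 1.0 - np.exp(-(t[task] - t1) / tau)
    end_level = 1.0 - np.exp(-(t2 - t1) / tau)
    rec = t > t2
    r[rec] = end_level * np.exp(-(t[rec] - t2) / tau)
    return r


def generate_subject(
    template: GroupTemplate,
    protocol: ProtocolSpec,
    rng: np.random.Generator,
    subject_id: str = "s01",
    condition: str = "blue",
    task_performance_mean: float = 58.0,
    task_performance_sd: float = 12.0,
) -> tuple[list[TimeSeriesRecord], float]:
    """Simulate all 14 channels plus task performance for one subject.

    The signal model per channel is
    ``baseline + a * onset_ramp(t) + drift_slope * t + noise`` where the
    subject amplitude ``a`` is drawn around the group mean. Task
    performance is a rounded Gaussian word count clipped at zero.
    """
    curve = _response_curve(protocol, template.onset_time_constant)
    n = len(curve)
    t = np.arange(n) / protocol.sampling_rate
    records = []
    for parameter in TIMESERIES_PARAMS:
        amp = rng.normal(template.response_amplitude[parameter],
                         template.sd_for(parameter))
        slope = rng.normal(0.0, template.drift_sd.get(parameter, 0.0)) / 60.0
        noise_sd = template.noise_sd.get(parameter, 0.0)
        noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
        samples = BASELINE_LEVELS[parameter] + amp * curve + slope * t + noise
        records.append(TimeSeriesRecord(
            subject_id=subject_id, condition=condition, parameter=parameter,
            sampling_rate=protocol.sampling_rate, samples=samples,
            phase_bounds=protocol.phase_bounds,
        ))
    perf = _draw_performance(rng, task_performance_mean, task_performance_sd)
    return records, perf


def _draw_performance(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(max(0.0, round(rng.normal(mean, sd))))


@dataclass
class ConditionData:
    """Simulated records for one condition, with ground truth attached."""

    condition: str
    records: dict[str, list[TimeSeriesRecord]]  # subject_id -> 14 channels
    task_performance: dict[str, float]
    labels: np.ndarray  # planted group index per subject, cohort order

    @property
    def subject_ids(self) -> list[str]:
        return list(self.records)

    @property
    def n_groups_realized(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class CohortData:
    spec: CohortSpec
    per_condition: dict[str, ConditionData]


def _subject_ids(n: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n)]


def _planted_label(rng: np.random.Generator, proportions: tuple[float, ...]) -> int:
    return int(rng.choice(len(proportions), p=proportions))


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate the full cohort: every subject in every condition."""
    ids = _subject_ids(spec.n_subjects)
    per_condition = {}
    for ci, cond in enumerate(spec.conditions):
        templates = spec.templates_per_condition[cond]
        props = spec.proportions(cond)
        records: dict[str, list[TimeSeriesRecord]] = {}
        perf: dict[str, float] = {}
        labels = np.empty(spec.n_subjects, dtype=int)
        for si, sid in enumerate(ids):
            rng = _subject_rng(spec.seed, ci, si)
            labels[si] = _planted_label(rng, props)
            recs, p = generate_subject(
                templates[labels[si]], spec.protocol, rng,
                subject_id=sid, condition=cond,
                task_performance_mean=spec.task_performance_mean,
                task_performance_sd=spec.task_performance_sd,
            )
            records[sid] = recs
            perf[sid] = p
        per_condition[cond] = ConditionData(cond, records, perf, labels)
    return CohortData(spec, per_condition)


# ---------------------------------------------------------------------------
# fast mode: draw AUC-level features directly

def _mixture_moments(
    templates: list[GroupTemplate], protocol: ProtocolSpec, separation: float
) -> tuple[np.ndarray, np.ndarray]:
    """Component means and within-group SDs of the implied AUC mixture.

    Means are (contrast-scaled) amplitude x task duration; the SD folds
    the between-subject amplitude jitter together with the residual
    trapezoidal-integration noise.
    """
    scaled = scale_template_contrast(templates, separation)
    T = protocol.task_duration
    fs = protocol.sampling_rate
    means = np.array([[t.response_amplitude[p] * T for p in TIMESERIES_PARAMS]
                      for t in scaled])
    sds = np.array([
        [math.hypot(t.sd_for(p) * T,
                    t.noise_sd.get(p, 0.0) * math.sqrt(T / fs))
         for p in TIMESERIES_PARAMS]
        for t in scaled
    ])
    return means, sds


def component_separation_sd(spec: CohortSpec, condition: str,
                            separation: float = 1.0,
                            features: tuple[str, ...] | None = None) -> float:
    """Smallest standardized distance between planted component means.

    Distances are Euclidean after dividing each feature axis by its
    within-group SD, minimized over group pairs — the effect size that
    governs how recoverable the planted partition is. ``features``
    restricts the computation to a feature subset (e.g. the combination
    actually clustered).
    """
    templates = spec.templates_per_condition[condition]
    means, sds = _mixture_moments(templates, spec.protocol, separation)
    if features is not None:
        idx = [TIMESERIES_PARAMS.index(f) for f in features]
        means, sds = means[:, idx], sds[:, idx]
    sd = sds.mean(axis=0)
    z = means / np.where(sd > 0, sd, 1.0)
    best = math.inf
    for i in range(len(z)):
        for j in range(i + 1, len(z)):
            best = min(best, float(np.linalg.norm(z[i] - z[j])))
    return best


def generate_feature_table(
    spec: CohortSpec, separation: float = 1.0
) -> tuple[dict[str, FeatureTable], dict[str, np.ndarray]]:
    """Draw per-condition feature tables from the implied AUC mixture.

    Returns ``(tables, labels)`` keyed by condition. Each table has the
    full 15-feature layout (14 AUC columns + task performance) and one
    row per subject; the mixture component of a row is its planted label.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    ids = _subject_ids(spec.n_subjects)
    tables: dict[str, FeatureTable] = {}
    labels_out: dict[str, np.ndarray] = {}
    for ci, cond in enumerate(spec.conditions):
        templates = spec.templates_per_condition[cond]
        props = spec.proportions(cond)
        means, sds = _mixture_moments(templates, spec.protocol, separation)
        rows = np.empty((spec.n_subjects, len(ALL_FEATURES)))
        labels = np.empty(spec.n_subjects, dtype=int)
        for si in range(spec.n_subjects):
            rng = _subject_rng(spec.seed, ci, si, stream=1)
            g = _planted_label(rng, props)
            labels[si] = g
            rows[si, :-1] = rng.normal(means[g], sds[g])
            rows[si, -1] = _draw_performance(rng, spec.task_performance_mean,
                                             spec.task_performance_sd)
        tables[cond] = FeatureTable(
            cond, pd.DataFrame(rows, index=ids, columns=list(ALL_FEATURES)),
            provenance="raw_auc",
        )
        labels_out[cond] = labels
    return tables, labels_out
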