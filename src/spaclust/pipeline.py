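"""End-to-end orchestration: data -> features -> normalization ->
combination search -> multi-method validity grid -> reports.

The pipeline reproduces the full analysis sequence on any of three
input modes (simulated cohort, a directory of per-subject time series,
or precomputed feature tables) and writes every report as delimited
text plus a JSON summary, so two runs with the same configuration are
byte-identical and any stage can be resumed from the previous stage's
files.
"""

from __future__ import annotations

import hashlib
import json
import platform
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .features import build_feature_table, correlation_table
from .methods import METHODS, adjusted_rand_index
from .records import FeatureTable, PFC_PARAMS, VC_PARAMS
from .reduction import ProjectedData, min_max_normalize, pca_project
from .search import (
    FeaturePools,
    search_combinations,
    score_combination,
    select_common_combinations,
)
from .synthetic import CohortSpec, default_cohort_spec, generate_cohort
from .validity import CRITERIA, ValidityReport, fraction_above, validity_report
from . import io as _io

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    input_mode: str = "simulate"  # simulate | timeseries_dir | feature_tables
    cohort: CohortSpec | None = None
    input_path: str | None = None
    feature_table_paths: dict[str, str] | None = None
    pools: FeaturePools = field(default_factory=FeaturePools)
    k_range: tuple[int, int] = (2, 9)
    silhouette_threshold: float = 0.6
    variance_threshold: float = 0.8
    methods: tuple[str, ...] = METHODS
    combination: tuple[str, ...] | None = None  # skip the search if fixed
    top_n: int = 5
    search_n_init: int = 10
    seed: int = 0
    output_dir: str | None = None
    exclude_subjects: tuple[str, ...] = ()
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.input_mode not in ("simulate", "timeseries_dir",
                                   "feature_tables"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        lo, hi = self.k_range
        if lo < 2 or hi < lo:
            raise ValueError(f"invalid k_range {self.k_range}")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.input_mode == "simulate" and self.cohort is None:
            self.cohort = default_cohort_spec(seed=_stage_seed(self.seed,
                                                               "simulate"))

    @property
    def ks(self) -> tuple[int, ...]:
        return tuple(range(self.k_range[0], self.k_range[1] + 1))

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    best_combination: tuple[str, ...]
    search_table: pd.DataFrame          # ranked common combinations
    validity_grid: dict[str, pd.DataFrame]  # condition -> methods x criteria
    method_reports: dict[str, dict[str, ValidityReport]]
    consensus: dict[str, int]           # headline consensus per condition
    projections: dict[str, ProjectedData]
    silhouettes: dict[str, np.ndarray]  # per subject, headline method
    labels: dict[str, np.ndarray]
    fraction_above_threshold: dict[str, float]
    ari_vs_planted: dict[str, float] | None
    correlations: pd.DataFrame
    provenance: dict


# ---------------------------------------------------------------------------
# stages

def _acquire_tables(config: PipelineConfig
                    ) -> tuple[dict[str, FeatureTable],
                               dict[str, np.ndarray] | None]:
    if config.input_mode == "simulate":
        cohort = generate_cohort(config.cohort)
        tables, labels = {}, {}
        for cond, data in cohort.per_condition.items():
            tables[cond] = build_feature_table(
                data.records, data.task_performance, cond)
            labels[cond] = data.labels
        return tables, labels
    if config.input_mode == "timeseries_dir":
        per_cond = _io.read_timeseries_dir(config.input_path)
        tables, labels = {}, {}
        for cond, data in per_cond.items():
            tables[cond] = build_feature_table(
                data.records, data.task_performance, cond)
            labels[cond] = data.labels if (data.labels >= 0).all() else None
        if any(v is None for v in labels.values()):
            labels = None
        return tables, labels
    tables = _io.read_feature_tables(config.feature_table_paths)
    return tables, None


def _drop_excluded(tables: dict[str, FeatureTable],
                   labels: dict[str, np.ndarray] | None,
                   exclude: tuple[str, ...]):
    if not exclude:
        return tables, labels
    out_t, out_l = {}, (None if labels is None else {})
    for cond, table in tables.items():
        keep = [s for s in table.subject_ids if s not in exclude]
        out_t[cond] = FeatureTable(cond, table.data.loc[keep],
                                   table.provenance)
        if labels is not None:
            mask = np.array([s not in exclude for s in table.subject_ids])
            out_l[cond] = labels[cond][mask]
    return out_t, out_l


def _search_stage(config: PipelineConfig,
                  normalized: dict[str, FeatureTable]
                  ) -> tuple[tuple[str, ...], pd.DataFrame]:
    seed = _stage_seed(config.seed, "search")
    if config.combination is not None:
        scores = [score_combination(normalized, tuple(config.combination),
                                    config.ks, seed,
                                    config.variance_threshold,
                                    config.search_n_init)]
        selected = scores
    else:
        scores = search_combinations(normalized, config.pools, config.ks,
                                     seed, config.variance_threshold,
                                     config.search_n_init)
        selected = select_common_combinations(
            scores, config.silhouette_threshold, config.top_n)
        if not selected:  # fall back to the best-ranked combo overall
            selected = sorted((s for s in scores if not s.failed),
                              key=lambda s: (-s.rank_score, s.features))[:1]
    rows = []
    for s in selected:
        row = {"features": ", ".join(s.features)}
        for cond in sorted(s.per_condition):
            sil, k = s.per_condition[cond]
            row[f"optimal_k_{cond}"] = k
            row[f"silhouette_{cond}"] = round(sil, 6)
        row["rank_score"] = round(s.rank_score, 6)
        rows.append(row)
    return selected[0].features, pd.DataFrame(rows)


def _validity_stage(config: PipelineConfig, projections: dict[str, ProjectedData]
                    ) -> tuple[dict[str, pd.DataFrame],
                               dict[str, dict[str, ValidityReport]]]:
    seed = _stage_seed(config.seed, "clustering")
    grids, reports = {}, {}
    for cond, proj in projections.items():
        per_method: dict[str, ValidityReport] = {}
        rows = []
        for method in config.methods:
            rep = validity_report(proj.scores, method, condition=cond,
                                  k_range=config.ks, seed=seed)
            per_method[method] = rep
            row = {"method": method}
            row.update({crit: rep.optimal_k_per_criterion[crit]
                        for crit in CRITERIA})
            row["consensus_k"] = rep.consensus_k
            rows.append(row)
        grids[cond] = pd.DataFrame(rows)
        reports[cond] = per_method
    return grids, reports


def _headline_method(config: PipelineConfig) -> str:
    return "kmeans" if "kmeans" in config.methods else config.methods[0]


def _correlation_stage(raw_tables: dict[str, FeatureTable],
                       combo: tuple[str, ...]) -> pd.DataFrame:
    cerebro = [f for f in combo if f in PFC_PARAMS + VC_PARAMS]
    systemic = [f for f in combo if f not in cerebro]
    frames = [correlation_table(raw_tables[cond], cerebro, systemic)
              for cond in sorted(raw_tables)]
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis and (optionally) write all artifacts."""
    raw_tables, planted = _acquire_tables(config)
    raw_tables, planted = _drop_excluded(raw_tables, planted,
                                         config.exclude_subjects)
    normalized = {cond: min_max_normalize(t) for cond, t in raw_tables.items()}

    best_combo, search_table = _search_stage(config, normalized)

    projections = {
        cond: pca_project(t.subset(best_combo), config.variance_threshold)
        for cond, t in normalized.items()
    }
    grids, reports = _validity_stage(config, projections)

    headline = _headline_method(config)
    consensus, silhouettes, labels, frac = {}, {}, {}, {}
    for cond in projections:
        rep = reports[cond][headline]
        consensus[cond] = rep.consensus_k
        silhouettes[cond] = rep.per_sample_silhouette_at_consensus
        labels[cond] = rep.labels_at_consensus
        vals = silhouettes[cond]
        frac[cond] = fraction_above(vals[np.isfinite(vals)],
                                    config.silhouette_threshold)

    ari = None
    if planted is not None:
        ari = {cond: adjusted_rand_index(planted[cond], labels[cond])
               for cond in labels}

    correlations = _correlation_stage(raw_tables, best_combo)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": {s: _stage_seed(config.seed, s)
                        for s in ("simulate", "search", "clustering")},
        "spaclust_version": __version__,
        "python_version": platform.python_version(),
        "n_subjects": {cond: len(t.data) for cond, t in raw_tables.items()},
        "best_combination": list(best_combo),
        "headline_method": headline,
    }

    report = RunReport(
        best_combination=best_combo, search_table=search_table,
        validity_grid=grids, method_reports=reports, consensus=consensus,
        projections=projections, silhouettes=silhouettes, labels=labels,
        fraction_above_threshold=frac, ari_vs_planted=ari,
        correlations=correlations, provenance=provenance,
    )
    if config.output_dir is not None:
        write_report(report, config)
    return report


def write_report(report: RunReport, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.search_table.to_csv(out / "search_table.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False,
                               float_format="%.6g")
    for cond, grid in report.validity_grid.items():
        grid.to_csv(out / f"validity_grid_{cond}.csv", index=False)
    for cond, proj in report.projections.items():
        frame = pd.DataFrame(
            proj.scores, index=proj.subject_ids,
            columns=[f"PC{i + 1}" for i in range(proj.n_components)])
        frame["cluster"] = report.labels[cond]
        frame["silhouette"] = np.round(report.silhouettes[cond], 6)
        frame.insert(0, "subject_id", frame.index)
        frame.to_csv(out / f"scores_{cond}.csv", index=False,
                     float_format="%.6g")
    summary = {
        "best_combination": list(report.best_combination),
        "consensus_k": report.consensus,
        "fraction_silhouette_above_threshold":
            {c: round(v, 6) for c, v in report.fraction_above_threshold.items()},
        "ari_vs_planted": report.ari_vs_planted,
        "provenance": report.provenance,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    if config.make_plots:
        _write_figures(report, out)


def _write_figures(report: RunReport, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cond, proj in report.projections.items():
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        sc = proj.scores
        y = sc[:, 1] if proj.n_components > 1 else np.zeros(len(sc))
        axes[0].scatter(sc[:, 0], y, c=report.labels[cond], cmap="tab10")
        for i, sid in enumerate(proj.subject_ids):
            axes[0].annotate(sid, (sc[i, 0], y[i]), fontsize=6)
        axes[0].set_xlabel("PC1")
        axes[0].set_ylabel("PC2" if proj.n_components > 1 else "")
        axes[0].set_title(f"PCA scores ({cond})")
        order = np.argsort(report.labels[cond])
        axes[1].barh(np.arange(len(order)), report.silhouettes[cond][order],
                     color="steelblue")
        axes[1].axvline(0.6, color="red", ls="--", lw=1)
        axes[1].set_xlabel("silhouette value")
        axes[1].set_title(f"per-subject silhouettes ({cond})")
        fig.tight_layout()
        fig.savefig(out / f"figure_{cond}.png", dpi=120)
        plt.close(fig)
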