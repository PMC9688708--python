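"""Plain-text serialization of cohorts, feature tables and configs.

Every artifact is delimited text or JSON so runs can be diffed and
resumed: one TSV per subject/condition (``time_s`` plus one column per
parameter) with a JSON sidecar carrying the phase boundaries, sampling
rate and — for synthetic cohorts — the planted label; feature tables
as one CSV per condition with a ``subject_id`` column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .records import ALL_FEATURES, TIMESERIES_PARAMS, FeatureTable, TimeSeriesRecord
from .synthetic import CohortData, ConditionData

__all__ = [
    "write_cohort",
    "read_timeseries_dir",
    "write_feature_table",
    "read_feature_table",
    "read_feature_tables",
]


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """One TSV + JSON sidecar per subject and condition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for cond, data in cohort.per_condition.items():
        for si, sid in enumerate(data.subject_ids):
            recs = data.records[sid]
            frame = pd.DataFrame({"time_s": recs[0].times})
            for rec in recs:
                frame[rec.parameter] = rec.samples
            stem = out / f"{cond}_{sid}"
            frame.to_csv(stem.with_suffix(".tsv"), sep="\t", index=False,
                         float_format="%.6f")
            meta = {
                "subject_id": sid,
                "condition": cond,
                "sampling_rate": recs[0].sampling_rate,
                "phase_bounds": list(recs[0].phase_bounds),
                "planted_label": int(data.labels[si]),
                "task_performance": data.task_performance[sid],
            }
            stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_timeseries_dir(path: str | Path) -> dict[str, ConditionData]:
    """Load a directory written by :func:`write_cohort` (or conforming
    external data) back into per-condition record sets."""
    path = Path(path)
    sidecars = sorted(path.glob("*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no sidecar metadata found in {path}")
    by_condition: dict[str, dict] = {}
    for sc in sidecars:
        meta = json.loads(sc.read_text())
        tsv = sc.with_suffix(".tsv")
        if not tsv.exists():
            raise FileNotFoundError(f"missing data file for sidecar {sc.name}")
        frame = pd.read_csv(tsv, sep="\t")
        if frame.empty:
            raise ValueError(f"{tsv.name}: empty data file")
        missing = [p for p in TIMESERIES_PARAMS if p not in frame.columns]
        if missing:
            raise ValueError(f"{tsv.name}: missing channels {missing}")
        cond, sid = meta["condition"], meta["subject_id"]
        recs = [
            TimeSeriesRecord(
                subject_id=sid, condition=cond, parameter=p,
                sampling_rate=float(meta["sampling_rate"]),
                samples=frame[p].to_numpy(dtype=float),
                phase_bounds=tuple(meta["phase_bounds"]),
            )
            for p in TIMESERIES_PARAMS
        ]
        slot = by_condition.setdefault(cond, {"records": {}, "perf": {},
                                              "labels": {}})
        slot["records"][sid] = recs
        slot["perf"][sid] = float(meta["task_performance"])
        slot["labels"][sid] = int(meta.get("planted_label", -1))
    out = {}
    for cond, slot in by_condition.items():
        sids = list(slot["records"])
        out[cond] = ConditionData(
            condition=cond, records=slot["records"],
            task_performance=slot["perf"],
            labels=np.array([slot["labels"][s] for s in sids], dtype=int),
        )
    return out


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    frame = table.data.copy()
    frame.insert(0, "subject_id", table.data.index)
    frame.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path: str | Path, condition: str,
                       provenance: str = "raw_auc") -> FeatureTable:
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ValueError(f"{path.name}: empty feature table")
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path.name}: missing subject_id column")
    frame = frame.set_index("subject_id")
    frame.index.name = None
    missing = [f for f in ALL_FEATURES if f not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing feature columns {missing}")
    non_numeric = [c for c in frame.columns
                   if not np.issubdtype(frame[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"{path.name}: non-numeric cells in {non_numeric}")
    return FeatureTable(condition, frame.astype(float), provenance=provenance)


def read_feature_tables(paths: Mapping[str, str | Path]
                        ) -> dict[str, FeatureTable]:
    """Load one feature table per condition; subject sets must agree
    across conditions so that every subject appears in every table."""
    tables = {cond: read_feature_table(p, cond) for cond, p in paths.items()}
    subject_sets = {cond: set(t.subject_ids) for cond, t in tables.items()}
    reference = next(iter(subject_sets.values()))
    for cond, sids in subject_sets.items():
        if sids != reference:
            odd = sorted(sids ^ reference)
            raise ValueError(
                f"inconsistent subject sets across conditions: {odd}")
    return tables
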