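#!/usr/bin/env python
"""Reduce each channel to its task-phase AUC and assemble the
15-feature table per condition.

Reads the cohort written by 01_simulate_cohort.py, subtracts the mean
of the final 120 s of baseline from each channel, integrates the task
phase with the trapezoid rule, and appends the task-performance count.
Writes results/features_<condition>.csv.
"""

from pathlib import Path

from spaclust.features import build_feature_table
from spaclust.io import read_timeseries_dir, write_feature_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    per_cond = read_timeseries_dir(ROOT.parent / "scratch" / "cohort")
    for cond, data in per_cond.items():
        table = build_feature_table(data.records, data.task_performance, cond)
        out = ROOT / f"features_{cond}.csv"
        write_feature_table(table, out)
        sc = table.data["SC"]
        print(f"{cond}: {table.data.shape[0]} subjects x "
              f"{table.data.shape[1]} features -> {out.name}; "
              f"SC AUC range [{sc.min():.0f}, {sc.max():.0f}] µS*s")


if __name__ == "__main__":
    main()
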