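#!/usr/bin/env python
"""Optimal cluster number for the best feature set, across all six
clustering methods and three validity criteria.

Takes the top combination from 03_search_combinations.py, projects it
per condition (min-max + PCA at 80% variance), runs k-means, k-medoids,
hierarchical (Ward), GMM, SOM and DBSCAN over k = 2..9 (epsilon grid
for DBSCAN), and tabulates each criterion's optimal k with the
two-out-of-three consensus — the methods x criteria grid. Also writes
per-subject PCA scores and silhouettes at the k-means consensus.
"""

import sys
from pathlib import Path

import pandas as pd

from spaclust.pipeline import PipelineConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    search = pd.read_csv(ROOT / "search_table.csv")
    best = tuple(search.iloc[0]["features"].split(", "))
    config = PipelineConfig(
        input_mode="feature_tables",
        feature_table_paths={c: str(ROOT / f"features_{c}.csv")
                             for c in ("blue", "red")},
        combination=best, seed=SEED, output_dir=str(ROOT / "validity"),
        make_plots=True,
    )
    report = run_pipeline(config)
    print(f"best combination: {', '.join(best)}")
    for cond, grid in report.validity_grid.items():
        print(f"\n-- {cond} light exposure --")
        print(grid.to_string(index=False))
        frac = report.fraction_above_threshold[cond]
        print(f"k-means consensus k = {report.consensus[cond]}; "
              f"{frac:.0%} of subjects with silhouette > 0.6")


if __name__ == "__main__":
    main()
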