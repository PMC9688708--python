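#!/usr/bin/env python
"""Exhaustive constrained 5-feature combination search.

Scores all 320 subsets (1 PFC x 1 VC x 3-of-6 systemic) per condition
by the best k-means silhouette over k = 2..9 on min-max + PCA-reduced
features, filters at silhouette > 0.6 in both conditions, and writes
the top-5 ranking (the best-common-combinations table) to
results/search_table.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from spaclust.io import read_feature_tables
from spaclust.reduction import min_max_normalize
from spaclust.search import search_combinations, select_common_combinations

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    tables = read_feature_tables({
        cond: ROOT / f"features_{cond}.csv" for cond in ("blue", "red")})
    normalized = {c: min_max_normalize(t) for c, t in tables.items()}
    scores = search_combinations(normalized, seed=SEED)
    selected = select_common_combinations(scores, threshold=0.6, top_n=5)
    rows = []
    for s in selected:
        row = {"features": ", ".join(s.features)}
        for cond in ("blue", "red"):
            sil, k = s.per_condition[cond]
            row[f"optimal_k_{cond}"] = k
            row[f"silhouette_{cond}"] = round(sil, 3)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.to_csv(ROOT / "search_table.csv", index=False)
    n_passing = sum(1 for s in scores if s.passes_threshold(0.6))
    print(f"{len(scores)} combinations scored, {n_passing} pass the "
          f"silhouette > 0.6 filter in both conditions; top 5:")
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
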