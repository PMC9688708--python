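#!/usr/bin/env python
"""Pearson correlations between the cerebrovascular and systemic
features of the best combination, per condition.

Cross-domain coupling (e.g. visual-cortex oxygenation vs. skin
conductance or end-tidal CO2) is what makes joint cerebral + systemic
clustering informative; this step quantifies it on the raw AUC tables
and writes results/correlations.csv.
"""

from pathlib import Path

import pandas as pd

from spaclust.features import correlation_table
from spaclust.io import read_feature_tables
from spaclust.records import PFC_PARAMS, VC_PARAMS

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    search = pd.read_csv(ROOT / "search_table.csv")
    best = tuple(search.iloc[0]["features"].split(", "))
    cerebro = [f for f in best if f in PFC_PARAMS + VC_PARAMS]
    systemic = [f for f in best if f not in cerebro]
    tables = read_feature_tables({
        cond: ROOT / f"features_{cond}.csv" for cond in ("blue", "red")})
    frames = [correlation_table(t, cerebro, systemic)
              for t in tables.values()]
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(ROOT / "correlations.csv", index=False,
               float_format="%.4f")
    sig = out[out["p"] < 0.05]
    print(out.to_string(index=False))
    print(f"\n{len(sig)}/{len(out)} pairs significant at p < 0.05")


if __name__ == "__main__":
    main()
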