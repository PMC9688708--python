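#!/usr/bin/env python
"""Simulate the study-design cohort and write it to disk.

30 subjects, two colored-light conditions (blue, red), 14 physiological
channels through an 8-min baseline / 9-min task / 15-min recovery
protocol at 1 Hz, plus a task-performance word count. Group structure:
3 planted reactivity groups under blue light, 5 under red.

Writes one TSV + JSON sidecar per subject/condition under
results/cohort/ and prints the realized group sizes.
"""

import sys
from pathlib import Path

import numpy as np

from spaclust.io import write_cohort
from spaclust.synthetic import default_cohort_spec, generate_cohort

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"


def main() -> None:
    spec = default_cohort_spec(seed=SEED)
    cohort = generate_cohort(spec)
    write_cohort(cohort, OUT)
    print(f"cohort seed={SEED}: {spec.n_subjects} subjects x "
          f"{len(spec.conditions)} conditions -> {OUT}")
    for cond, data in cohort.per_condition.items():
        sizes = np.bincount(data.labels)
        print(f"  {cond}: {data.n_groups_realized} planted groups, "
              f"sizes {sizes.tolist()}")


if __name__ == "__main__":
    main()
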