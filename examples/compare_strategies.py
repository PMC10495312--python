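"""Compare the three strategy arms on a small synthetic cohort.

Runs AIZE, the non-weighted (plain per-location ZEST) and the
fixed-weight (0.33) comparators on four fields under two error
conditions, and prints per-arm medians of test length and accuracy.
The expected pattern: fixed weighting is fastest, AIZE second; AIZE is
the most accurate on damaged fields.
"""

import numpy as np

from aize import (
    ERROR_CONDITIONS,
    make_study_cohort,
    median_across_conditions,
    run_experiment,
    study_plan,
)

cohort = make_study_cohort(np.random.default_rng(0))
subset = [f for f in cohort if f.field_id in ("N02", "N05", "G04", "G06")]

plan = study_plan(subset, base_seed=1, repetitions=10,
                  conditions=ERROR_CONDITIONS[:2])
table = run_experiment(plan)

for metric in ("presentations", "rmse"):
    print(f"\nmedian {metric} (median of per-condition medians):")
    out = median_across_conditions(table, metric)
    for _, row in out.iterrows():
        print(f"  {row['strategy']:14s} {row['field_label']:9s} "
              f"{row['median_of_condition_medians']:7.1f}")
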