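"""Evaluation metrics: RMSE, presentation-count summaries, test-retest
binning, input-vs-estimate limits, paired comparisons.

Accuracy is the root mean square error (RMSE) between true (input)
sensitivities and estimates over the grid; speed is the total number of
stimulus presentations per test.  Test-retest variability is summarized
by binning per-location across-repetition RMSEs, and estimator bias by
the distribution of estimates conditional on true sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .grid import TestGrid
from .harness import ExperimentTable

__all__ = [
    "trial_rmse",
    "attach_rmse",
    "condition_summaries",
    "median_across_conditions",
    "RetestSummary",
    "retest_binning",
    "sensitivity_limits",
    "paired_comparison",
]


def _included(grid: TestGrid, exclude_blind_spot: bool) -> np.ndarray:
    if not exclude_blind_spot:
        return np.ones(len(grid), dtype=bool)
    return np.array([not loc.blind_spot_adjacent for loc in grid])


def trial_rmse(estimates, true_field, grid: TestGrid, exclude_blind_spot: bool = True) -> float:
    """RMSE between estimated and true sensitivities over one trial, dB.

    Blind-spot-adjacent locations are excluded by default (the
    convention for global field indices).
    """
    est = np.asarray(estimates, dtype=float)
    truth = np.asarray(
        true_field.sensitivity if hasattr(true_field, "sensitivity") else true_field, dtype=float
    )
    if est.shape != (len(grid),) or truth.shape != (len(grid),):
        raise ValueError("estimates and truth must cover every grid location")
    if np.any(np.isnan(est)):
        raise ValueError("missing estimate")
    inc = _included(grid, exclude_blind_spot)
    return float(np.sqrt(np.mean((est[inc] - truth[inc]) ** 2)))


def attach_rmse(table: ExperimentTable, exclude_blind_spot: bool = True) -> pd.DataFrame:
    """Trials frame with an `rmse` column added (vectorized over trials)."""
    inc = _included(table.grid, exclude_blind_spot)
    truth = np.stack([table.truths[fid] for fid in table.trials["field_id"]])
    err = (table.estimates - truth)[:, inc]
    out = table.trials.copy()
    out["rmse"] = np.sqrt(np.mean(err**2, axis=1))
    return out


def condition_summaries(table: ExperimentTable, exclude_blind_spot: bool = True) -> pd.DataFrame:
    """Medians and IQRs of RMSE and presentations per strategy arm.

    One row per (strategy, field_label, condition) plus a pooled row per
    (strategy, field_label) with condition "all".
    """
    df = attach_rmse(table, exclude_blind_spot)

    def summarize(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_trials": len(g),
                "rmse_median": g["rmse"].median(),
                "rmse_q25": g["rmse"].quantile(0.25),
                "rmse_q75": g["rmse"].quantile(0.75),
                "presentations_median": g["total_presentations"].median(),
                "presentations_q25": g["total_presentations"].quantile(0.25),
                "presentations_q75": g["total_presentations"].quantile(0.75),
            }
        )

    per_cond = (
        df.groupby(["strategy", "field_label", "condition"])
        .apply(summarize, include_groups=False)
        .reset_index()
    )
    pooled = (
        df.groupby(["strategy", "field_label"]).apply(summarize, include_groups=False).reset_index()
    )
    pooled["condition"] = "all"
    return pd.concat([per_cond, pooled], ignore_index=True)


def median_across_conditions(
    table: ExperimentTable, metric: str = "rmse", exclude_blind_spot: bool = True
) -> pd.DataFrame:
    """The headline summary: median over the per-condition medians.

    For each (strategy, field_label): take the median of `metric` within
    each error condition, then the median of those five values.  The
    pooled-over-all-trials median is reported alongside, since the two
    poolings can differ.
    """
    df = attach_rmse(table, exclude_blind_spot)
    col = {"rmse": "rmse", "presentations": "total_presentations"}[metric]
    per_cond = df.groupby(["strategy", "field_label", "condition"])[col].median().reset_index()
    out = (
        per_cond.groupby(["strategy", "field_label"])[col]
        .median()
        .rename("median_of_condition_medians")
        .reset_index()
    )
    pooled = (
        df.groupby(["strategy", "field_label"])[col].median().rename("pooled_median").reset_index()
    )
    return out.merge(pooled, on=["strategy", "field_label"])


@dataclass
class RetestSummary:
    """Test-retest variability: per-location across-repetition RMSE bins."""

    cell_rmse: pd.DataFrame   # strategy, field_label, field_id, condition, location, rmse
    histogram: pd.DataFrame   # strategy, field_label, bin_left, count
    exceed_count: pd.DataFrame  # strategy, field_label, n_locations_rmse_gt_threshold
    threshold: float
    bin_width: float


def retest_binning(
    table: ExperimentTable,
    bin_width: float = 1.0,
    threshold: float = 7.0,
    exclude_blind_spot: bool = True,
) -> RetestSummary:
    """Bin test-retest RMSE at the same location.

    For each (strategy, field, condition, location) cell the RMSE of the
    repeated estimates against the true sensitivity is computed across
    repetitions; cells are histogrammed per strategy and cohort, and the
    number of cells with RMSE above `threshold` (default 7 dB, the large-
    variability criterion) is reported.  Requires >= 2 repetitions.
    """
    if table.trials.groupby(["strategy", "field_id", "condition"])["rep"].count().min() < 2:
        raise ValueError("retest binning requires at least 2 repetitions per cell")
    inc = _included(table.grid, exclude_blind_spot)
    loc_idx = np.flatnonzero(inc)
    records = []
    keys = ["strategy", "field_id", "condition"]
    for (strategy, fid, cond), g in table.trials.groupby(keys):
        truth = table.truths[fid][loc_idx]
        est = table.estimates[g.index.to_numpy()][:, loc_idx]
        rmse = np.sqrt(np.mean((est - truth) ** 2, axis=0))
        label = table.field_labels.get(fid, "unknown")
        for loc, val in zip(loc_idx, rmse):
            records.append(
                {"strategy": strategy, "field_label": label, "field_id": fid,
                 "condition": cond, "location": int(loc), "rmse": float(val)}
            )
    cells = pd.DataFrame(records)
    n_bins = max(int(np.ceil(cells["rmse"].max() / bin_width)), 1)
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
    hist_rows = []
    for (strategy, label), g in cells.groupby(["strategy", "field_label"]):
        counts, _ = np.histogram(g["rmse"], bins=edges)
        for left, c in zip(edges[:-1], counts):
            hist_rows.append(
                {"strategy": strategy, "field_label": label,
                 "bin_left": float(left), "count": int(c)}
            )
    exceed = (
        cells.assign(exceed=cells["rmse"] > threshold)
        .groupby(["strategy", "field_label"])["exceed"]
        .sum()
        .rename("n_locations_rmse_gt_threshold")
        .reset_index()
    )
    return RetestSummary(
        cell_rmse=cells,
        histogram=pd.DataFrame(hist_rows),
        exceed_count=exceed,
        threshold=threshold,
        bin_width=bin_width,
    )


def sensitivity_limits(
    table: ExperimentTable,
    quantiles=(0.05, 0.25, 0.50, 0.75, 0.95),
    exclude_blind_spot: bool = True,
) -> pd.DataFrame:
    """Distribution of estimates conditional on true input sensitivity.

    Estimates are grouped by rounded true sensitivity (dB) per strategy;
    the requested quantiles describe estimator bias and spread across the
    sensitivity range (the simulation-sensitivity-limit view).
    """
    inc = _included(table.grid, exclude_blind_spot)
    truth = np.stack([table.truths[fid] for fid in table.trials["field_id"]])[:, inc]
    est = table.estimates[:, inc]
    strategies = table.trials["strategy"].to_numpy()
    rows = []
    for strategy in pd.unique(strategies):
        sel = strategies == strategy
        t = np.round(truth[sel].ravel()).astype(int)
        e = est[sel].ravel()
        for level in np.unique(t):
            vals = e[t == level]
            row = {"strategy": strategy, "true_db": int(level), "n": int(vals.size)}
            for q in quantiles:
                row[f"q{int(round(q * 100)):02d}"] = float(np.quantile(vals, q))
            rows.append(row)
    return pd.DataFrame(rows)


def paired_comparison(values_a, values_b):
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Returns (statistic, p_value).  All-zero differences are a degenerate
    case: a warning is issued and (0.0, 1.0) returned.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if np.allclose(a, b):
        warnings.warn("all paired differences are zero; signed-rank test is degenerate")
        return 0.0, 1.0
    res = wilcoxon(a, b)
    return float(res.statistic), float(res.pvalue)
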