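"""Figure analogues: presentation/RMSE boxplots, retest histograms,
estimate-vs-truth limits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .harness import ExperimentTable  # noqa: E402
from .metrics import RetestSummary, attach_rmse, sensitivity_limits  # noqa: E402

__all__ = ["plot_condition_boxes", "plot_retest_histogram", "plot_sensitivity_limits"]


def plot_condition_boxes(table: ExperimentTable, metric: str = "total_presentations", out=None):
    """Per-condition boxplots of presentations or RMSE, one panel per cohort."""
    df = attach_rmse(table) if metric == "rmse" else table.trials
    labels = sorted(df["field_label"].unique())
    strategies = list(df["strategy"].unique())
    conditions = list(df["condition"].unique())
    fig, axes = plt.subplots(1, len(labels), figsize=(6 * len(labels), 4), squeeze=False)
    width = 0.8 / len(strategies)
    for ax, label in zip(axes[0], labels):
        sub = df[df["field_label"] == label]
        for si, strategy in enumerate(strategies):
            data = [
                sub[(sub["strategy"] == strategy) & (sub["condition"] == c)][metric]
                for c in conditions
            ]
            pos = np.arange(len(conditions)) + si * width
            ax.boxplot(data, positions=pos, widths=width * 0.9, showfliers=False)
        ax.set_xticks(np.arange(len(conditions)) + 0.4)
        ax.set_xticklabels(conditions, rotation=30)
        ax.set_title(f"{label} fields")
        ax.set_ylabel(metric)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig


def plot_retest_histogram(summary: RetestSummary, out=None):
    """Counts of test locations by test-retest RMSE, per strategy and cohort."""
    labels = sorted(summary.histogram["field_label"].unique())
    fig, axes = plt.subplots(len(labels), 1, figsize=(7, 3.2 * len(labels)), squeeze=False)
    for ax, label in zip(axes[:, 0], labels):
        sub = summary.histogram[summary.histogram["field_label"] == label]
        for strategy, g in sub.groupby("strategy"):
            ax.step(g["bin_left"], g["count"], where="post", label=strategy)
        ax.set_xlabel("test-retest RMSE (dB)")
        ax.set_ylabel("locations")
        ax.set_title(f"{label} fields")
        ax.legend()
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig


def plot_sensitivity_limits(table: ExperimentTable, out=None):
    """Median and 5-95% band of estimates vs true input sensitivity."""
    lims = sensitivity_limits(table)
    strategies = list(lims["strategy"].unique())
    fig, axes = plt.subplots(1, len(strategies), figsize=(4.5 * len(strategies), 4), squeeze=False)
    for ax, strategy in zip(axes[0], strategies):
        g = lims[lims["strategy"] == strategy].sort_values("true_db")
        ax.plot(g["true_db"], g["q50"], "k-", label="median")
        ax.fill_between(g["true_db"], g["q05"], g["q95"], alpha=0.2, label="5-95%")
        ax.fill_between(g["true_db"], g["q25"], g["q75"], alpha=0.35, label="IQR")
        ax.plot(g["true_db"], g["true_db"], "r:", label="identity")
        ax.set_xlabel("true sensitivity (dB)")
        ax.set_ylabel("estimate (dB)")
        ax.set_title(strategy)
        ax.legend(fontsize=8)
    fig.tight_layout()
    if out:
        fig.savefig(out, dpi=120)
        plt.close(fig)
    return fig
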