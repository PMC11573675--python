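"""Figure panels for the standard summaries.

Thin matplotlib wrappers: binned learning curves per phase and probe
type, transfer accuracy by condition and probed size (the crossover
panel), and model-comparison bars (criterion means and best-fit
frequencies). Each function draws on a provided/created Axes and
returns the Figure, leaving styling and saving to the caller.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .behavior_stats import AccuracySummary

__all__ = [
    "plot_learning_curves",
    "plot_transfer_crossover",
    "plot_model_comparison",
]


def plot_learning_curves(bins: AccuracySummary):
    """Binned accuracy over trials, one panel per phase."""
    phases = list(bins.summary["phase"].unique())
    fig, axes = plt.subplots(1, len(phases), figsize=(4 * len(phases), 3), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, phase in zip(axes, phases):
        sub = bins.summary[bins.summary["phase"] == phase]
        for ptype, grp in sub.groupby("probe_type"):
            ax.errorbar(
                grp["bin"] + 1, grp["mean"], yerr=grp["sem"], marker="o",
                capsize=2, label=ptype,
            )
        ax.axhline(0.5, ls="--", c="gray", lw=0.8)
        ax.set_title(f"{phase} learning")
        ax.set_xlabel("trial bin")
        ax.set_xticks(sorted(sub["bin"].unique() + 1))
    axes[0].set_ylabel("P(correct)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    return fig


def plot_transfer_crossover(table: pd.DataFrame):
    """Transfer accuracy by prior condition and probed size, per probe type."""
    transfer = table[table["phase"] == "transfer"]
    per = (
        transfer.groupby(["probe_type", "condition", "probed_size", "subject_id"])
        ["accuracy"].mean().rename("acc").reset_index()
    )
    ptypes = list(per["probe_type"].unique())
    fig, axes = plt.subplots(1, len(ptypes), figsize=(4 * len(ptypes), 3), sharey=True)
    axes = np.atleast_1d(axes)
    conds = ["prior4cycle", "prior6cycle"]
    for ax, ptype in zip(axes, ptypes):
        sub = per[per["probe_type"] == ptype]
        for size, color in ((4, "tab:green"), (6, "black")):
            means = [
                sub[(sub.condition == c) & (sub.probed_size == size)]["acc"].mean()
                for c in conds
            ]
            sems = [
                sub[(sub.condition == c) & (sub.probed_size == size)]["acc"].sem()
                for c in conds
            ]
            ax.errorbar(
                range(len(conds)), means, yerr=sems, marker="o", color=color,
                label=f"{size}-cycle probes", capsize=3,
            )
        ax.axhline(0.5, ls="--", c="gray", lw=0.8)
        ax.set_xticks(range(len(conds)), ["4-cycle prior", "6-cycle prior"])
        ax.set_title(f"{ptype} probes")
    axes[0].set_ylabel("P(correct)")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    return fig


def plot_model_comparison(report: pd.DataFrame, criterion: str = "waic"):
    """Criterion means per variant, differences to the best, best-fit counts."""
    means = report.groupby("spec")[criterion].mean()
    order = [s for s in means.sort_index().index]
    best_per_subject = report.loc[
        report.groupby("subject_id")[criterion].idxmin(), "spec"
    ]
    counts = best_per_subject.value_counts(normalize=True).reindex(order).fillna(0)
    fig, axes = plt.subplots(1, 3, figsize=(13, 3))
    axes[0].bar(order, means[order])
    axes[0].set_ylabel(f"mean {criterion.upper()}")
    axes[1].bar(order, means[order] - means.min())
    axes[1].set_ylabel(f"Δ{criterion.upper()} vs best")
    axes[2].bar(order, counts[order])
    axes[2].set_ylabel("best-fit frequency")
    for ax in axes:
        ax.tick_params(axis="x", rotation=75, labelsize=7)
    fig.tight_layout()
    return fig
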