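"""Descriptive behavioral statistics: learning curves, trends, interaction.

These summaries mirror the figures of the study design the simulator
emulates: binned accuracy curves per phase and probe type (four bins of
12 prior / 9 transfer trials), per-subject logistic trends of accuracy
over trials, and the condition x probed-size interaction contrast during
transfer with a subject-level bootstrap CI. Group summaries always
average within subject first, then across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AccuracySummary",
    "InteractionResult",
    "StatsError",
    "bin_accuracy",
    "trend_per_subject",
    "interaction_contrast",
]

#: Logistic-scale slopes are clipped to this magnitude (quasi-separation).
SLOPE_BOUND = 10.0


class StatsError(ValueError):
    """Raised for invalid statistics inputs."""


@dataclass
class AccuracySummary:
    """Binned accuracy: group-level summary plus the per-subject means."""

    summary: pd.DataFrame  # phase, probe_type, bin, mean, sem, n, trials_per_bin
    per_subject: pd.DataFrame  # subject_id, phase, probe_type, bin, acc


def bin_accuracy(table: pd.DataFrame, n_bins: int = 4) -> AccuracySummary:
    """Trial-binned accuracy per phase and probe type.

    Trials of each phase are split into ``n_bins`` equal consecutive
    bins (48 prior trials -> bins of 12; 36 transfer trials -> bins of
    9); probed sizes are averaged within participant first. Raises if a
    phase's trial count is not divisible by ``n_bins``.
    """
    df = table.copy()
    rows = []
    for phase, grp in df.groupby("phase"):
        n_trials = int(grp["trial"].max())
        if n_trials % n_bins != 0:
            raise StatsError(
                f"{n_trials} {phase} trials do not divide into {n_bins} bins"
            )
        width = n_trials // n_bins
        grp = grp.assign(bin=(grp["trial"] - 1) // width, trials_per_bin=width)
        rows.append(grp)
    df = pd.concat(rows)
    per_subject = (
        df.groupby(["subject_id", "phase", "probe_type", "bin"])["accuracy"]
        .mean()
        .rename("acc")
        .reset_index()
    )
    summary = (
        per_subject.groupby(["phase", "probe_type", "bin"])["acc"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
    )
    widths = df.groupby("phase")["trials_per_bin"].first()
    summary["trials_per_bin"] = summary["phase"].map(widths)
    return AccuracySummary(summary=summary, per_subject=per_subject)


def _logistic_trend(trials: np.ndarray, acc: np.ndarray) -> tuple[float, bool]:
    """Two-parameter logistic fit of correctness on trial number."""
    if len(np.unique(acc)) == 1:
        # all-identical outcomes: the slope is unidentified (the intercept
        # diverges); report 0 and flag rather than a spurious bound value
        return 0.0, True
    X = sm.add_constant(trials.astype(float))
    try:
        res = sm.Logit(acc, X).fit(disp=0, maxiter=200)
        slope = float(res.params[1])
    except Exception:
        return 0.0, True
    if abs(slope) > SLOPE_BOUND:
        return float(np.clip(slope, -SLOPE_BOUND, SLOPE_BOUND)), True
    return slope, False


def trend_per_subject(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject temporal trend of accuracy, per phase and probe type.

    Returns one row per (subject, phase, probe_type) with the
    logistic-scale slope per trial, its probability-scale per-trial
    change evaluated at the subject's mean accuracy
    (``slope * p * (1 - p)``), and a flag for degenerate or clipped
    fits.
    """
    rows = []
    for (sid, phase, ptype), grp in table.groupby(
        ["subject_id", "phase", "probe_type"]
    ):
        grp = grp.dropna(subset=["chosen"])
        if grp["trial"].nunique() < 2:
            raise StatsError(
                f"need >= 2 trials for a trend: {sid}/{phase}/{ptype}"
            )
        acc = grp["accuracy"].to_numpy(dtype=float)
        slope, flagged = _logistic_trend(grp["trial"].to_numpy(), acc)
        p = acc.mean()
        rows.append(
            {
                "subject_id": sid,
                "phase": phase,
                "probe_type": ptype,
                "slope": slope,
                "prob_change_per_trial": slope * p * (1 - p),
                "mean_accuracy": p,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class InteractionResult:
    """Condition x probed-size interaction on transfer accuracy."""

    contrast: float
    ci_low: float
    ci_high: float
    diff_size4: float  # mean4(prior4cycle) - mean4(prior6cycle)
    diff_size6: float  # mean6(prior4cycle) - mean6(prior6cycle)
    n_subjects: dict
    n_boot: int
    seed: int

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


def interaction_contrast(
    table: pd.DataFrame, n_boot: int = 10_000, seed: int = 0
) -> InteractionResult:
    """Disordinal interaction contrast with a subject-level bootstrap CI.

    On transfer-phase rows, each subject contributes a mean accuracy per
    probed size (pooled over probe types); the contrast is
    ``[mean4(prior4cycle) - mean4(prior6cycle)] - [mean6(prior4cycle) -
    mean6(prior6cycle)]``. Subjects are resampled with replacement
    within condition (percentile CI). A positive contrast with both
    simple differences of opposite sign is the crossover expected when
    prior subprocess knowledge is reused.
    """
    df = table[table["phase"] == "transfer"]
    per = (
        df.groupby(["condition", "subject_id", "probed_size"])["accuracy"]
        .mean()
        .unstack("probed_size")
    )
    for cond in ("prior4cycle", "prior6cycle"):
        if cond not in per.index.get_level_values("condition"):
            raise StatsError(f"missing condition cell: {cond}")
    for size in (4, 6):
        if size not in per.columns or per[size].isna().any():
            raise StatsError(f"missing probed-size cell: {size}")
    mats = {
        cond: per.loc[cond][[4, 6]].to_numpy()
        for cond in ("prior4cycle", "prior6cycle")
    }

    def contrast_of(m4: np.ndarray, m6: np.ndarray) -> float:
        d4 = m4[:, 0].mean() - m6[:, 0].mean()
        d6 = m4[:, 1].mean() - m6[:, 1].mean()
        return d4 - d6

    m4, m6 = mats["prior4cycle"], mats["prior6cycle"]
    diff4 = float(m4[:, 0].mean() - m6[:, 0].mean())
    diff6 = float(m4[:, 1].mean() - m6[:, 1].mean())
    rng = np.random.default_rng(seed)
    idx4 = rng.integers(len(m4), size=(n_boot, len(m4)))
    idx6 = rng.integers(len(m6), size=(n_boot, len(m6)))
    boot = (
        m4[idx4, 0].mean(axis=1) - m6[idx6, 0].mean(axis=1)
    ) - (m4[idx4, 1].mean(axis=1) - m6[idx6, 1].mean(axis=1))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return InteractionResult(
        contrast=float(contrast_of(m4, m6)),
        ci_low=float(lo),
        ci_high=float(hi),
        diff_size4=diff4,
        diff_size6=diff6,
        n_subjects={"prior4cycle": len(m4), "prior6cycle": len(m6)},
        n_boot=n_boot,
        seed=seed,
    )
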