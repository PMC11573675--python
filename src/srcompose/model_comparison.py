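"""Information-criterion model comparison and posterior simulation.

WAIC needs pointwise log-likelihoods under posterior draws, but the
models are fitted by maximum likelihood. The bridge is a Laplace
approximation: a Gaussian centred at the MLE with covariance from the
finite-difference curvature of the negative log-likelihood, truncated to
the parameter box. AIC is reported alongside as a deterministic
alternative; every report labels which metric a number uses.

Posterior simulations rerun the generative agents at each subject's
fitted parameters and summarize accuracy per condition x probed size x
probe type, including the across-condition differences whose signs
carry the transfer signature (higher accuracy on the probed size whose
cycle was already experienced in the subject's prior condition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess

from . import sr_models
from .fitting import (
    FitResult,
    ModelSpec,
    _aligned_accuracy,
    _pointwise_from_acc,
    enumerate_model_space,
)
from .task_graphs import TaskProtocol

__all__ = [
    "waic",
    "aic",
    "laplace_draws",
    "subject_report",
    "model_frequencies",
    "posterior_simulate",
    "ComparisonError",
]


class ComparisonError(ValueError):
    """Raised for invalid model-comparison inputs."""


def waic(pointwise_loglik_draws: np.ndarray) -> tuple[float, float, float]:
    """Widely applicable information criterion from pointwise draws.

    ``pointwise_loglik_draws`` has one row per posterior draw and one
    column per observation. Returns ``(waic, lppd, p_waic)`` with
    ``lppd = sum_i log mean_s exp(ll_is)`` (computed log-stably),
    ``p_waic = sum_i var_s(ll_is)`` (population variance, so replicating
    the set of draws leaves the value unchanged) and
    ``waic = -2 (lppd - p_waic)``.
    """
    draws = np.asarray(pointwise_loglik_draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ComparisonError("need a draws x observations matrix with >= 2 draws")
    if not np.isfinite(draws).all():
        raise ComparisonError("non-finite pointwise log-likelihoods")
    S = draws.shape[0]
    lppd = float((logsumexp(draws, axis=0) - np.log(S)).sum())
    p_waic = float(draws.var(axis=0).sum())
    return -2.0 * (lppd - p_waic), lppd, p_waic


def aic(fit: FitResult) -> float:
    """Akaike information criterion, ``2k + 2 NLL`` at the MLE."""
    return 2.0 * fit.model_spec.n_free + 2.0 * fit.nll


def _gaussian_param_draws(
    nll_fn,
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    n_draws: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Laplace-approximate parameter draws, truncated to the box bounds.

    The covariance is the inverse finite-difference Hessian of the
    negative log-likelihood at ``x0``; a non-positive-definite curvature
    falls back to a diagonal-jittered version and is flagged.
    """
    x0 = np.asarray(x0, dtype=float)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def safe_nll(x):
        return nll_fn(np.clip(x, lo, hi))

    flags: list[str] = []
    H = approx_hess(x0, safe_nll)
    H = 0.5 * (H + H.T)
    eigvals = np.linalg.eigvalsh(H)
    if eigvals.min() <= 0:
        # curvature can be flat or indefinite at a bound; regularize
        H = H + (abs(eigvals.min()) + 1e-3) * np.eye(len(x0))
        flags.append("hessian_jittered")
    cov = np.linalg.inv(H)
    draws = rng.multivariate_normal(x0, cov, size=n_draws, method="svd")
    return np.clip(draws, lo, hi), flags


def laplace_draws(
    fit: FitResult,
    model_spec: ModelSpec,
    subject_data: pd.DataFrame,
    protocol: TaskProtocol,
    n_draws: int = 1000,
    seed: int = 0,
    n_restarts: int = 5,
) -> tuple[np.ndarray, list[str]]:
    """Pointwise log-likelihood draws under the Laplace posterior at the MLE.

    Returns a ``(n_draws, n_answered_probes)`` matrix (each row is one
    parameter draw replayed through the subject's session) plus any
    flags from the curvature computation. Seeded and deterministic.
    """
    if n_draws < 1:
        raise ComparisonError("n_draws must be >= 1")
    acc = _aligned_accuracy(subject_data, protocol)

    def nll_fn(v: np.ndarray) -> float:
        params = model_spec.to_params(v)
        return float(
            -_pointwise_from_acc(params, model_spec, acc, protocol, n_restarts).sum()
        )

    rng = np.random.default_rng(seed)
    param_draws, flags = _gaussian_param_draws(
        nll_fn, fit.mle_vector, model_spec.bounds, n_draws, rng
    )
    out = np.empty((n_draws, int(np.sum(~np.isnan(acc)))))
    for s in range(n_draws):
        params = model_spec.to_params(param_draws[s])
        out[s] = _pointwise_from_acc(params, model_spec, acc, protocol, n_restarts)
    return out, flags


# ---------------------------------------------------------------------------
# cohort-level reports


def subject_report(
    fit: FitResult,
    subject_data: pd.DataFrame,
    protocol: TaskProtocol,
    n_draws: int = 1000,
    seed: int = 0,
    n_restarts: int = 5,
) -> dict:
    """One subject x model row: WAIC (Laplace), AIC, effective parameters."""
    draws, flags = laplace_draws(
        fit, fit.model_spec, subject_data, protocol, n_draws, seed, n_restarts
    )
    w, lppd, p_w = waic(draws)
    return {
        "subject_id": fit.subject_id,
        "model": fit.model_spec.model,
        "spec": fit.model_spec.name,
        "n_free": fit.model_spec.n_free,
        "nll": fit.nll,
        "waic": w,
        "lppd": lppd,
        "p_waic": p_w,
        "aic": aic(fit),
        "flags": ";".join(flags + fit.flags),
    }


def model_frequencies(
    report: pd.DataFrame, criterion: str = "waic"
) -> tuple[pd.Series, pd.Series]:
    """Best-fit proportions per model variant and per model class.

    ``report`` needs one row per subject x variant with columns
    ``subject_id``, ``spec``, ``model``, ``n_free`` and the criterion
    column. Every subject must carry all 12 variants. Exact criterion
    ties go to the variant with fewer parameters. Returns
    ``(variant_frequencies, class_frequencies)``; each sums to 1.
    """
    if criterion not in report.columns:
        raise ComparisonError(f"criterion column '{criterion}' missing")
    specs = [s.name for s in enumerate_model_space()]
    counts = pd.Series(0.0, index=specs)
    for sid, grp in report.groupby("subject_id"):
        if sorted(grp["spec"]) != sorted(specs):
            raise ComparisonError(
                f"subject {sid} does not have entries for all 12 variants"
            )
        ordered = grp.sort_values([criterion, "n_free"], kind="mergesort")
        counts[ordered.iloc[0]["spec"]] += 1
    freq = counts / counts.sum()
    class_freq = freq.groupby(
        freq.index.map(lambda name: name.split("_")[0])
    ).sum()
    return freq, class_freq


def posterior_simulate(
    fits: Mapping[str, FitResult],
    protocols: Mapping[str, TaskProtocol],
    n_reps: int = 10,
    seed: int = 0,
    n_restarts: int = 5,
) -> "PosteriorSimulation":
    """Simulate sessions at each subject's MLE and summarize accuracy.

    Every subject is rerun ``n_reps`` times through their own protocol
    at their fitted parameters. Cell summaries average within subject
    first; the across-condition differences are computed on the transfer
    phase for each probed size (and probe type), the data feature whose
    disordinal pattern separates the transfer model from its ablations.
    """
    if set(fits) - set(protocols):
        raise ComparisonError("missing protocol for some fitted subjects")
    frames = []
    for i, sid in enumerate(sorted(fits)):
        fit = fits[sid]
        protocol = protocols[sid]
        for rep in range(n_reps):
            rng = np.random.default_rng(np.random.SeedSequence((seed, i, rep)))
            rec, _ = sr_models.run_agent(
                fit.model_spec, fit.mle_params, protocol, rng, n_restarts
            )
            rec["subject_id"] = sid
            rec["condition"] = protocol.condition
            rec["rep"] = rep
            frames.append(rec)
    sim = pd.concat(frames, ignore_index=True)
    keys = ["condition", "phase", "probe_type", "probed_size"]
    per_subject = (
        sim.groupby(["subject_id"] + keys)["accuracy"].mean().rename("acc")
    ).reset_index()
    cells = (
        per_subject.groupby(keys)["acc"]
        .agg(mean="mean", sem="sem", n="count")
        .reset_index()
    )
    transfer = cells[cells["phase"] == "transfer"]
    diff_rows = []
    for (ptype, size), grp in transfer.groupby(["probe_type", "probed_size"]):
        by_cond = grp.set_index("condition")["mean"]
        if {"prior4cycle", "prior6cycle"} - set(by_cond.index):
            continue
        diff_rows.append(
            {
                "probe_type": ptype,
                "probed_size": size,
                "across_condition_diff": float(
                    by_cond["prior4cycle"] - by_cond["prior6cycle"]
                ),
            }
        )
    return PosteriorSimulation(
        cells=cells, across_condition=pd.DataFrame(diff_rows), table=sim
    )


@dataclass
class PosteriorSimulation:
    """Accuracy summaries from posterior simulations."""

    cells: pd.DataFrame
    across_condition: pd.DataFrame
    table: pd.DataFrame
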