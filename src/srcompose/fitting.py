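"""Per-subject maximum-likelihood fitting over the 12-model variant space.

The model space crosses the three agent classes (compound SR, feature
SR, feature SR with transfer) with 1 vs 2 learning rates (shared or
phase-specific alpha) and 1 vs 2 softmax temperatures (shared or
probe-type-specific tau); the transfer model adds the reuse weight
omega. Likelihoods deterministically replay the subject's observation
stream with the same kernels the generative agents use, so the
probability assigned to each observed choice is exactly the probability
the agent would have sampled from.

Optimization is derivative-free (Nelder-Mead) in a sigmoid-transformed
unconstrained space with seeded multi-start, because the transfer
model's discrete permutation step makes the likelihood piecewise smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from . import sr_models
from .sr_models import ModelError, Params
from .task_graphs import TaskProtocol

__all__ = [
    "ModelSpec",
    "FitResult",
    "FitError",
    "enumerate_model_space",
    "negative_log_likelihood",
    "pointwise_loglik",
    "fit_subject",
    "PARAM_BOUNDS",
    "PROB_CLIP",
]

#: Box bounds used for fitting (and for truncating posterior draws).
PARAM_BOUNDS = {
    "alpha": (1e-4, 1.0),
    "tau": (1e-3, 20.0),
    "omega": (0.0, 1.0),
}

#: Choice probabilities are clipped to this range inside log-likelihoods.
PROB_CLIP = 1e-9


class FitError(ValueError):
    """Raised for data/protocol misalignment or invalid fitting inputs."""


@dataclass(frozen=True)
class ModelSpec:
    """One model variant: agent class x learning-rate count x tau count."""

    model: str
    n_alphas: int
    n_taus: int

    def __post_init__(self) -> None:
        if self.model not in ("M1", "M2", "M3"):
            raise ModelError(f"unknown model {self.model!r}")
        if self.n_alphas not in (1, 2) or self.n_taus not in (1, 2):
            raise ModelError("n_alphas and n_taus must be 1 or 2")

    @property
    def name(self) -> str:
        return f"{self.model}_{self.n_alphas}a{self.n_taus}t"

    @property
    def free_names(self) -> tuple[str, ...]:
        names: list[str] = (
            ["alpha"] if self.n_alphas == 1 else ["alpha_prior", "alpha_transfer"]
        )
        names += ["tau"] if self.n_taus == 1 else ["tau_exp", "tau_inf"]
        if self.model == "M3":
            names.append("omega")
        return tuple(names)

    @property
    def n_free(self) -> int:
        return self.n_alphas + self.n_taus + (1 if self.model == "M3" else 0)

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple(
            PARAM_BOUNDS[name.split("_")[0]] for name in self.free_names
        )

    def to_params(self, x: Sequence[float], gamma: float = sr_models.GAMMA_DEFAULT) -> Params:
        """Expand a free-parameter vector into a full Params (tied = equal)."""
        x = list(map(float, x))
        if len(x) != self.n_free:
            raise ModelError(
                f"{self.name} expects {self.n_free} free parameters, got {len(x)}"
            )
        vals = dict(zip(self.free_names, x))
        if self.n_alphas == 1:
            vals["alpha_prior"] = vals["alpha_transfer"] = vals.pop("alpha")
        if self.n_taus == 1:
            vals["tau_exp"] = vals["tau_inf"] = vals.pop("tau")
        if self.model != "M3":
            vals["omega"] = None
        return Params(gamma=gamma, **vals)


def enumerate_model_space() -> list[ModelSpec]:
    """The 3 x 2 x 2 = 12 model variants, in stable order."""
    return [
        ModelSpec(model, n_alphas, n_taus)
        for model in ("M1", "M2", "M3")
        for n_alphas in (1, 2)
        for n_taus in (1, 2)
    ]


# ---------------------------------------------------------------------------
# data/protocol alignment and likelihood


def _aligned_accuracy(
    subject_data: pd.DataFrame, protocol: TaskProtocol
) -> np.ndarray:
    """Observed accuracy per protocol probe, NaN where unanswered.

    The table slice must contain exactly the protocol's probes, keyed by
    (phase, trial, probe_type); cue and option labels are checked so a
    table cannot silently be scored against the wrong session.
    """
    probes = protocol.all_probes()
    keyed = {}
    for _, row in subject_data.iterrows():
        key = (row["phase"], int(row["trial"]), row["probe_type"])
        if key in keyed:
            raise FitError(f"duplicate probe rows for {key}")
        keyed[key] = row
    acc = np.full(len(probes), np.nan)
    for i, q in enumerate(probes):
        key = (q.phase, q.trial + 1, q.probe_type)
        if key not in keyed:
            raise FitError(f"missing probe row for {key}")
        row = keyed[key]
        data = protocol.phase(q.phase)
        expected = (
            q.cue.label(data.f1, data.f2),
            q.option_correct.label(data.f1, data.f2),
            q.option_lure.label(data.f1, data.f2),
        )
        got = (row["cue"], row["option_correct"], row["option_lure"])
        if got != expected:
            raise FitError(
                f"probe mismatch at {key}: data shows {got}, "
                f"protocol expects {expected}"
            )
        if pd.notna(row["chosen"]):
            acc[i] = 1.0 if row["chosen"] == "correct" else 0.0
    return acc


def _pointwise_from_acc(
    params: Params,
    model_spec,
    acc: np.ndarray,
    protocol: TaskProtocol,
    n_restarts: int,
) -> np.ndarray:
    p_all = sr_models.probe_probabilities(
        model_spec, params, protocol, n_restarts
    )
    answered = ~np.isnan(acc)
    p = p_all[answered]
    p_chosen = np.where(acc[answered] == 1.0, p, 1.0 - p)
    return np.log(np.clip(p_chosen, PROB_CLIP, 1 - PROB_CLIP))


def pointwise_loglik(
    params: Params,
    model_spec,
    subject_data: pd.DataFrame,
    protocol: TaskProtocol,
    n_restarts: int = 5,
) -> np.ndarray:
    """Log-likelihood of each answered probe under a deterministic replay."""
    acc = _aligned_accuracy(subject_data, protocol)
    return _pointwise_from_acc(params, model_spec, acc, protocol, n_restarts)


def negative_log_likelihood(
    params: Params,
    model_spec,
    subject_data: pd.DataFrame,
    protocol: TaskProtocol,
    n_restarts: int = 5,
) -> float:
    """Negative log-likelihood of a subject's observed choices."""
    return float(
        -pointwise_loglik(params, model_spec, subject_data, protocol, n_restarts).sum()
    )


# ---------------------------------------------------------------------------
# multi-start bounded optimization


@dataclass
class FitResult:
    """MLE fit of one model variant to one subject."""

    subject_id: str
    model_spec: ModelSpec
    mle_params: Params
    mle_vector: np.ndarray  # free parameters, natural scale
    nll: float
    pointwise: np.ndarray  # per-answered-probe log-likelihood at the MLE
    n_starts: int
    converged: bool
    seed: int
    flags: list[str] = field(default_factory=list)

    @property
    def n_probes(self) -> int:
        return len(self.pointwise)


def _to_natural(x: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + (hi - lo) * expit(x)


def _to_unconstrained(v: np.ndarray, bounds) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    frac = np.clip((np.asarray(v) - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return logit(frac)


def _start_points(
    spec: ModelSpec, n_starts: int, rng: np.random.Generator
) -> np.ndarray:
    """Seeded natural-scale random starting points.

    Learning rates and omega are drawn uniformly; temperatures are drawn
    log-uniformly over [0.03, 3] because choice behavior is most
    sensitive to tau on that scale given SR values of order one.
    """
    starts = np.empty((n_starts, spec.n_free))
    for j, name in enumerate(spec.free_names):
        kind = name.split("_")[0]
        if kind == "tau":
            starts[:, j] = np.exp(rng.uniform(np.log(0.03), np.log(3.0), n_starts))
        else:
            starts[:, j] = rng.uniform(0.05, 0.95, n_starts)
    return starts


#: Coarse deterministic pre-scan grid used to place simplex starts. The
#: likelihood is multimodal in the learning rates (the transfer model's
#: permutation step switches basins discretely), so starts are taken from
#: the best grid points rather than drawn blindly.
_SCAN_GRID = {
    "alpha": (0.05, 0.1, 0.15, 0.22, 0.3, 0.4, 0.55, 0.75),
    "tau": (0.05, 0.12, 0.25, 0.5, 1.2),
    "omega": (0.05, 0.25, 0.5, 0.75, 0.95),
}


def _prescan_starts(
    spec: ModelSpec,
    acc: np.ndarray,
    protocol: TaskProtocol,
    n_best: int,
    n_restarts: int,
) -> np.ndarray:
    """Best grid points by NLL, exploiting that replay depends only on alphas."""
    answered = ~np.isnan(acc)
    chose_correct = acc[answered] == 1.0
    alphas = _SCAN_GRID["alpha"]
    taus = _SCAN_GRID["tau"]
    omegas = _SCAN_GRID["omega"] if spec.model == "M3" else (None,)
    alpha_combos = (
        [(a,) for a in alphas]
        if spec.n_alphas == 1
        else [(a, b) for a in alphas for b in alphas]
    )
    tau_combos = (
        [(t,) for t in taus]
        if spec.n_taus == 1
        else [(te, ti) for te in taus for ti in taus]
    )
    scored: list[tuple[float, tuple[float, ...]]] = []
    for ac in alpha_combos:
        a_p, a_t = (ac[0], ac[0]) if len(ac) == 1 else ac
        parts = sr_models.probe_value_parts(
            spec, a_p, a_t, protocol, n_restarts=n_restarts
        )
        is_inf = parts.is_inference[answered]
        for om in omegas:
            vc, vl = parts.values(om)
            dv = (vc - vl)[answered]
            for tc in tau_combos:
                te, ti = (tc[0], tc[0]) if len(tc) == 1 else tc
                p = expit(dv / np.where(is_inf, ti, te))
                p_chosen = np.where(chose_correct, p, 1.0 - p)
                nll = -np.log(np.clip(p_chosen, PROB_CLIP, 1.0)).sum()
                vec = ac + tc + ((om,) if om is not None else ())
                scored.append((float(nll), vec))
    scored.sort(key=lambda t: t[0])
    return np.array([vec for _, vec in scored[:n_best]])


def fit_subject(
    model_spec: ModelSpec,
    subject_data: pd.DataFrame,
    protocol: TaskProtocol,
    n_starts: int = 20,
    seed: int = 0,
    n_restarts: int = 5,
    maxfev: int = 500,
    extra_starts: Sequence[Sequence[float]] | None = None,
) -> FitResult:
    """Fit one model variant to one subject by multi-start Nelder-Mead.

    The ``n_starts`` simplex starts are the best points of a
    deterministic coarse parameter grid (scored cheaply by reusing the
    replay's value components), topped up with seeded random draws if
    the grid is smaller than ``n_starts``. The search runs in a
    sigmoid-transformed unconstrained space so the box bounds (alpha in
    [1e-4, 1], tau in [1e-3, 20], omega in [0, 1]) are respected
    exactly. Deterministic given ``seed``. A fit where no start
    converged is returned flagged, not raised.
    """
    if n_starts < 1:
        raise FitError("n_starts must be >= 1")
    bounds = model_spec.bounds
    acc = _aligned_accuracy(subject_data, protocol)  # fail fast on misalignment
    if np.isnan(acc).all():
        raise FitError("subject has no answered probes")

    def nll_of_vector(v: np.ndarray) -> float:
        params = model_spec.to_params(v)
        return float(
            -_pointwise_from_acc(
                params, model_spec, acc, protocol, n_restarts
            ).sum()
        )

    def objective(x: np.ndarray) -> float:
        return nll_of_vector(_to_natural(x, bounds))

    rng = np.random.default_rng(seed)
    starts = _prescan_starts(model_spec, acc, protocol, n_starts, n_restarts)
    if len(starts) < n_starts:
        starts = np.vstack(
            [starts, _start_points(model_spec, n_starts - len(starts), rng)]
        )
    if extra_starts is not None:
        # warm starts, e.g. a nested variant's expanded optimum
        starts = np.vstack([np.atleast_2d(np.asarray(extra_starts)), starts])
    best_x = None
    best_nll = np.inf
    any_converged = False
    for start in starts:
        x0 = _to_unconstrained(start, bounds)
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxfev": maxfev},
        )
        any_converged = any_converged or bool(res.success)
        if res.fun < best_nll:
            best_nll = float(res.fun)
            best_x = res.x
    assert best_x is not None
    v = _to_natural(best_x, bounds)
    params = model_spec.to_params(v)
    pw = _pointwise_from_acc(params, model_spec, acc, protocol, n_restarts)
    subject_id = (
        str(subject_data["subject_id"].iloc[0])
        if "subject_id" in subject_data.columns
        else ""
    )
    flags = [] if any_converged else ["no_start_converged"]
    return FitResult(
        subject_id=subject_id,
        model_spec=model_spec,
        mle_params=params,
        mle_vector=v,
        nll=float(-pw.sum()),
        pointwise=pw,
        n_starts=n_starts,
        converged=any_converged,
        seed=seed,
        flags=flags,
    )
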