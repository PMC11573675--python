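"""Successor predictive agents for the product-graph task.

Three model classes share a temporal-difference successor learning rule
and a softmax binary choice rule:

* **M1 — successor compound model.** Learns expected discounted future
  occupancy over whole compound stimuli. Held-out compounds are never
  experienced, so their rows stay at the identity and inference probes
  are answered at exactly 50%.
* **M2 — successor feature model.** Decomposes each compound into its
  two features and learns a 10x10 expected future feature-occupancy
  matrix per phase, with no integration between phases.
* **M3 — successor feature model with transfer.** Same learning as M2,
  plus a permutation mapping between prior- and transfer-phase features
  that maximizes the similarity (Frobenius inner product) of the two
  successor matrices. Transfer-phase choices use the mixture
  ``omega * permuted_prior + (1 - omega) * transfer``.

The SR convention is self-inclusive with identity initialization: the
update drives row ``s`` toward ``e_s + gamma * M[s']``, so diagonals are
nonzero even for never-experienced states and every entry lies in
``[0, 1/(1-gamma)]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from . import _replay
from .task_graphs import TaskProtocol

__all__ = [
    "Params",
    "SRMatrix",
    "AgentState",
    "MappingResult",
    "ModelError",
    "update_compound_sr",
    "update_feature_sr",
    "option_value",
    "choice_prob",
    "find_mapping",
    "apply_mapping",
    "combine_sr",
    "probe_values",
    "probe_probabilities",
    "run_agent",
    "GAMMA_DEFAULT",
]

ModelName = Literal["M1", "M2", "M3"]

#: Discount for future occupancy; fixed (not fitted) and configurable.
GAMMA_DEFAULT = 0.9


class ModelError(ValueError):
    """Raised for invalid model parameters or inputs."""


@dataclass(frozen=True)
class Params:
    """Agent parameters.

    ``alpha_prior`` / ``alpha_transfer`` are phase-specific learning
    rates in (0, 1]; ``tau_exp`` / ``tau_inf`` are softmax temperatures
    (values are divided by tau) for experience and inference probes;
    ``omega`` in [0, 1] weights the permuted prior representation in M3
    and must be None for M1/M2; ``gamma`` is the shared discount.
    """

    alpha_prior: float
    alpha_transfer: float
    tau_exp: float
    tau_inf: float
    omega: float | None = None
    gamma: float = GAMMA_DEFAULT

    def __post_init__(self) -> None:
        if not (0 < self.alpha_prior <= 1 and 0 < self.alpha_transfer <= 1):
            raise ModelError("learning rates must lie in (0, 1]")
        if self.tau_exp <= 0 or self.tau_inf <= 0:
            raise ModelError("softmax temperatures must be positive")
        if self.omega is not None and not (0 <= self.omega <= 1):
            raise ModelError("omega must lie in [0, 1]")
        if not (0 <= self.gamma < 1):
            raise ModelError("gamma must lie in [0, 1)")

    def validate_for(self, model: ModelName) -> None:
        if model == "M3":
            if self.omega is None:
                raise ModelError("M3 requires omega")
        elif self.omega is not None:
            raise ModelError(f"omega supplied to {model}")


@dataclass
class SRMatrix:
    """A successor matrix with labelled rows/columns."""

    labels: tuple[str, ...]
    values: np.ndarray

    @classmethod
    def identity(cls, labels: Sequence[str]) -> "SRMatrix":
        labels = tuple(labels)
        return cls(labels=labels, values=np.eye(len(labels)))

    @property
    def index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def loc(self, unit: str | int) -> int:
        if isinstance(unit, (int, np.integer)):
            if not 0 <= unit < len(self.labels):
                raise ModelError(f"index {unit} out of range")
            return int(unit)
        try:
            return self.index[unit]
        except KeyError:
            raise ModelError(f"unknown unit {unit!r}") from None


@dataclass
class AgentState:
    """A model's final representations after a session."""

    model: ModelName
    sr_prior: SRMatrix
    sr_transfer: SRMatrix
    params: Params
    mapping: dict[str, str] | None = None  # prior feature -> transfer feature


# ---------------------------------------------------------------------------
# elementary operations (functional; the compiled kernels inline the same math)


def update_compound_sr(
    M: SRMatrix, s: str | int, s_next: str | int, alpha: float, gamma: float
) -> SRMatrix:
    """One TD successor update of row ``s`` toward ``e_s + gamma * M[s_next]``."""
    i, j = M.loc(s), M.loc(s_next)
    V = M.values.copy()
    target = gamma * V[j]
    target[i] += 1.0
    V[i] += alpha * (target - V[i])
    return SRMatrix(labels=M.labels, values=V)


def update_feature_sr(
    M: SRMatrix,
    feats: tuple[str | int, str | int],
    feats_next: tuple[str | int, str | int],
    alpha: float,
    gamma: float,
) -> SRMatrix:
    """One successor-feature update of both current-feature rows.

    Each row in ``feats`` moves toward the two-hot indicator of the
    current features plus ``gamma`` times the mean of the two successor
    feature rows (mean, not sum, so entries keep the ``1/(1-gamma)``
    bound).
    """
    i1, i2 = (M.loc(f) for f in feats)
    j1, j2 = (M.loc(f) for f in feats_next)
    V = M.values.copy()
    target = gamma * 0.5 * (V[j1] + V[j2])
    target[i1] += 1.0
    target[i2] += 1.0
    for i in (i1, i2):
        V[i] = V[i] + alpha * (target - V[i])
    return SRMatrix(labels=M.labels, values=V)


def option_value(
    M: SRMatrix,
    cue: str | int | tuple,
    option: str | int | tuple,
    model: ModelName,
) -> float:
    """Value of an answer option given a cue under a model's readout.

    M1 reads a single compound-to-compound entry; M2/M3 sum the four
    feature-to-feature entries between the cue's and the option's
    feature pairs.
    """
    if model == "M1":
        return float(M.values[M.loc(cue), M.loc(option)])
    ci = [M.loc(f) for f in cue]
    oi = [M.loc(f) for f in option]
    return float(sum(M.values[i, j] for i in ci for j in oi))


def choice_prob(v_correct: float, v_lure: float, tau: float) -> float:
    """Softmax probability of choosing the correct option (temperature tau)."""
    if tau <= 0:
        raise ModelError("tau must be positive")
    return float(expit((v_correct - v_lure) / tau))


# ---------------------------------------------------------------------------
# permutation mapping


@dataclass(frozen=True)
class MappingResult:
    """A feature bijection and its achieved similarity objective."""

    perm: np.ndarray  # perm[i] = transfer index assigned to prior feature i
    objective: float
    method: str

    def as_dict(
        self, prior_labels: Sequence[str], transfer_labels: Sequence[str]
    ) -> dict[str, str]:
        return {
            prior_labels[i]: transfer_labels[int(p)]
            for i, p in enumerate(self.perm)
        }


def _as_array(M: SRMatrix | np.ndarray) -> np.ndarray:
    return M.values if isinstance(M, SRMatrix) else np.asarray(M, dtype=float)


def _block_permutations(blocks: Sequence[int]):
    """All bijections that map each factor's block onto itself."""
    offsets = np.cumsum([0] + list(blocks[:-1]))
    per_block = [
        [np.array(p) + off for p in itertools.permutations(range(size))]
        for size, off in zip(blocks, offsets)
    ]
    for combo in itertools.product(*per_block):
        yield tuple(np.concatenate(combo))


def _exhaustive_mapping(
    A: np.ndarray, B: np.ndarray, blocks: Sequence[int] | None = None
) -> MappingResult:
    n = A.shape[0]
    if blocks is None and n > 9:
        raise ModelError("exhaustive search is limited to <= 9 features")
    best_obj = -np.inf
    best_perm: np.ndarray | None = None
    chunk = 20000
    it = (
        itertools.permutations(range(n))
        if blocks is None
        else _block_permutations(blocks)
    )
    while True:
        block = np.array(list(itertools.islice(it, chunk)), dtype=np.int64)
        if block.size == 0:
            break
        gathered = B[block[:, :, None], block[:, None, :]]
        objs = np.einsum("ij,pij->p", A, gathered)
        k = int(np.argmax(objs))  # first maximum: lexicographic tie-break
        if objs[k] > best_obj:
            best_obj = float(objs[k])
            best_perm = block[k]
    assert best_perm is not None
    return MappingResult(perm=best_perm, objective=best_obj, method="exhaustive")


def find_mapping(
    M_prior: SRMatrix | np.ndarray,
    M_transfer: SRMatrix | np.ndarray,
    method: str = "exhaustive",
    rng: np.random.Generator | None = None,
    n_restarts: int = 20,
    blocks: Sequence[int] | None = None,
) -> MappingResult:
    """Find the bijection maximizing ``<P M_prior P^T, M_transfer>``.

    Since permutation preserves the Frobenius norm of ``M_prior``, this
    is equivalent to minimizing the Frobenius distance between the
    permuted prior matrix and the transfer matrix. ``exhaustive``
    enumerates all bijections (exact, lexicographic tie-break);
    ``local_search`` runs best-improvement pairwise-swap hill climbing
    from an identity start plus seeded random restarts and reports its
    achieved objective (ties keep the earliest restart).

    ``blocks`` optionally constrains the search to bijections mapping
    each factor's feature block onto itself (e.g. ``(4, 6)``: 4-factor
    features onto 4-factor features, 6 onto 6); the default
    unconstrained search is the purely data-driven mechanism.
    """
    A = _as_array(M_prior)
    B = _as_array(M_transfer)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ModelError(
            f"matrices must be square and equal-sized, got {A.shape} vs {B.shape}"
        )
    n = A.shape[0]
    if blocks is not None and sum(blocks) != n:
        raise ModelError(f"blocks {blocks} do not partition {n} features")
    if method == "exhaustive":
        return _exhaustive_mapping(A, B, blocks)
    if method != "local_search":
        raise ModelError(f"unknown mapping method {method!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    if blocks is None:
        restarts = np.empty((n_restarts, n), dtype=np.int64)
        restarts[0] = np.arange(n)
        for r in range(1, n_restarts):
            restarts[r] = rng.permutation(n)
        perm, obj = _replay.hill_climb_restarts(A, B, restarts)
        return MappingResult(perm=perm, objective=float(obj), method="local_search")
    # constrained search: swaps restricted to within-block pairs
    offsets = np.cumsum([0] + list(blocks[:-1]))
    pairs = [
        (int(off + i), int(off + j))
        for size, off in zip(blocks, offsets)
        for i in range(size - 1)
        for j in range(i + 1, size)
    ]
    best_perm, best_obj = None, -np.inf
    for r in range(n_restarts):
        if r == 0:
            perm = np.arange(n)
        else:
            perm = np.concatenate(
                [off + rng.permutation(size) for size, off in zip(blocks, offsets)]
            ).astype(np.int64)
        obj = _replay.qap_objective(A, B, perm)
        improved = True
        while improved:
            improved = False
            deltas = [(_replay._swap_delta(A, B, perm, u, v), u, v) for u, v in pairs]
            d, u, v = max(deltas)
            if d > 1e-10:
                perm[u], perm[v] = perm[v], perm[u]
                obj += d
                improved = True
        if obj > best_obj + 1e-10:
            best_obj, best_perm = float(obj), perm.copy()
    return MappingResult(perm=best_perm, objective=best_obj, method="local_search")


def apply_mapping(M_prior: SRMatrix | np.ndarray, perm: np.ndarray) -> np.ndarray:
    """Relabel the prior matrix into transfer coordinates: ``P M P^T``."""
    A = _as_array(M_prior)
    out = np.empty_like(A)
    out[np.ix_(perm, perm)] = A
    return out


def combine_sr(
    M_prior_mapped: SRMatrix | np.ndarray,
    M_transfer: SRMatrix | np.ndarray,
    omega: float,
) -> np.ndarray:
    """Elementwise mixture ``omega * mapped_prior + (1 - omega) * transfer``."""
    if not 0 <= omega <= 1:
        raise ModelError("omega must lie in [0, 1]")
    A = _as_array(M_prior_mapped)
    B = _as_array(M_transfer)
    if A.shape != B.shape:
        raise ModelError("matrices must share their indexing")
    return omega * A + (1 - omega) * B


# ---------------------------------------------------------------------------
# full-session replay


def _model_name(model_spec) -> ModelName:
    name = getattr(model_spec, "model", model_spec)
    if name not in ("M1", "M2", "M3"):
        raise ModelError(f"unknown model {name!r}")
    return name


@dataclass
class ValueParts:
    """Per-probe option-value components, dependent on learning rates only.

    For M3 transfer probes the final values mix the permuted-prior part
    (``vc_map``/``vl_map``) with the direct transfer part via omega; for
    everything else the two parts coincide, so
    ``v = omega * v_map + (1 - omega) * v_dir`` holds uniformly (with
    any omega for M1/M2). The softmax temperature enters only after the
    mixture, which lets fitting scan tau and omega cheaply at a fixed
    pair of learning rates.
    """

    vc_map: np.ndarray
    vl_map: np.ndarray
    vc_dir: np.ndarray
    vl_dir: np.ndarray
    is_inference: np.ndarray
    M_prior: np.ndarray
    M_transfer: np.ndarray
    perm: np.ndarray | None

    def values(self, omega: float | None) -> tuple[np.ndarray, np.ndarray]:
        w = 0.0 if omega is None else omega
        return (
            w * self.vc_map + (1 - w) * self.vc_dir,
            w * self.vl_map + (1 - w) * self.vl_dir,
        )

    def p_correct(
        self, omega: float | None, tau_exp: float, tau_inf: float
    ) -> np.ndarray:
        vc, vl = self.values(omega)
        tau = np.where(self.is_inference, tau_inf, tau_exp)
        return expit((vc - vl) / tau)


def probe_value_parts(
    model_spec,
    alpha_prior: float,
    alpha_transfer: float,
    protocol: TaskProtocol,
    gamma: float = GAMMA_DEFAULT,
    n_restarts: int = 5,
) -> ValueParts:
    """Run the compiled replay kernels at the given learning rates."""
    model = _model_name(model_spec)
    plan = _replay.get_plan(protocol)
    pp, tp = plan.prior, plan.transfer
    perm = None
    if model == "M1":
        vc_p, vl_p, M_p = _replay.sr_compound_replay(
            pp.obs_c, pp.upd, pp.probe_pos, pp.cue_c, pp.corr_c, pp.lure_c,
            pp.n_states, alpha_prior, gamma,
        )
        vc_t, vl_t, M_t = _replay.sr_compound_replay(
            tp.obs_c, tp.upd, tp.probe_pos, tp.cue_c, tp.corr_c, tp.lure_c,
            tp.n_states, alpha_transfer, gamma,
        )
        vcm_t, vlm_t = vc_t, vl_t
    else:
        vc_p, vl_p, M_p = _replay.sr_feature_replay(
            pp.obs_f, pp.upd, pp.probe_pos, pp.cue_f, pp.corr_f, pp.lure_f,
            alpha_prior, gamma,
        )
        if model == "M2":
            vc_t, vl_t, M_t = _replay.sr_feature_replay(
                tp.obs_f, tp.upd, tp.probe_pos, tp.cue_f, tp.corr_f, tp.lure_f,
                alpha_transfer, gamma,
            )
            vcm_t, vlm_t = vc_t, vl_t
        else:
            restarts = _replay.mapping_restarts(
                protocol.seed, protocol.n_transfer_trials, n_restarts
            )
            vcm_t, vlm_t, vc_t, vl_t, M_t, perm = _replay.sr_transfer_replay(
                tp.obs_f, tp.upd, tp.probe_pos, tp.probe_trial,
                tp.cue_f, tp.corr_f, tp.lure_f,
                M_p, restarts, alpha_transfer, gamma,
            )
    return ValueParts(
        vc_map=np.concatenate([vc_p, vcm_t]),
        vl_map=np.concatenate([vl_p, vlm_t]),
        vc_dir=np.concatenate([vc_p, vc_t]),
        vl_dir=np.concatenate([vl_p, vl_t]),
        is_inference=plan.is_inference(),
        M_prior=M_p,
        M_transfer=M_t,
        perm=perm,
    )


def probe_probabilities(
    model_spec,
    params: Params,
    protocol: TaskProtocol,
    n_restarts: int = 5,
) -> np.ndarray:
    """Per-probe probability of the correct option, chronological order.

    Numpy-only fast path shared by the likelihood; equals the
    ``p_correct`` column of :func:`probe_values`.
    """
    model = _model_name(model_spec)
    params.validate_for(model)
    parts = probe_value_parts(
        model_spec, params.alpha_prior, params.alpha_transfer, protocol,
        params.gamma, n_restarts,
    )
    return parts.p_correct(params.omega, params.tau_exp, params.tau_inf)


def probe_values(
    model_spec,
    params: Params,
    protocol: TaskProtocol,
    n_restarts: int = 5,
):
    """Deterministically replay a session; return per-probe option values.

    Returns ``(values, state)`` where ``values`` is a DataFrame with one
    row per probe in chronological order (columns ``phase``, ``trial``,
    ``probe_type``, ``probed_size``, ``v_correct``, ``v_lure``,
    ``p_correct``) and ``state`` is the final :class:`AgentState`. The
    mapping model recomputes its permutation from the current transfer
    matrix before each trial's probes, from restart permutations seeded
    by the protocol seed, so replay is reproducible without consuming
    any caller-side randomness.
    """
    model = _model_name(model_spec)
    params.validate_for(model)
    parts = probe_value_parts(
        model_spec, params.alpha_prior, params.alpha_transfer, protocol,
        params.gamma, n_restarts,
    )
    if model == "M1":
        labels_p = _compound_labels(protocol, "prior")
        labels_t = _compound_labels(protocol, "transfer")
    else:
        labels_p = _feature_labels(protocol, "prior")
        labels_t = _feature_labels(protocol, "transfer")

    plan = _replay.get_plan(protocol)
    vc, vl = parts.values(params.omega)
    frames = []
    offset = 0
    for phase, pl in (("prior", plan.prior), ("transfer", plan.transfer)):
        n = len(pl.probe_pos)
        frames.append(
            pd.DataFrame(
                {
                    "phase": phase,
                    "trial": pl.probe_trial + 1,
                    "probe_type": np.where(
                        pl.is_inference, "inference", "experience"
                    ),
                    "probed_size": pl.probed_size,
                    "v_correct": vc[offset : offset + n],
                    "v_lure": vl[offset : offset + n],
                }
            )
        )
        offset += n
    values = pd.concat(frames, ignore_index=True)
    values["p_correct"] = parts.p_correct(
        params.omega, params.tau_exp, params.tau_inf
    )
    state = AgentState(
        model=model,
        sr_prior=SRMatrix(labels=labels_p, values=parts.M_prior),
        sr_transfer=SRMatrix(labels=labels_t, values=parts.M_transfer),
        params=params,
        mapping=(
            MappingResult(
                perm=parts.perm, objective=float("nan"), method="local_search"
            ).as_dict(labels_p, labels_t)
            if parts.perm is not None
            else None
        ),
    )
    return values, state


def _compound_labels(protocol: TaskProtocol, phase: str) -> tuple[str, ...]:
    data = protocol.phase(phase)
    return tuple(
        data.f1.labels[a] + data.f2.labels[b]
        for a in range(data.f1.size)
        for b in range(data.f2.size)
    )


def _feature_labels(protocol: TaskProtocol, phase: str) -> tuple[str, ...]:
    data = protocol.phase(phase)
    return data.f1.labels + data.f2.labels


def run_agent(
    model_spec,
    params: Params,
    protocol: TaskProtocol,
    rng: np.random.Generator,
    n_restarts: int = 5,
) -> tuple[pd.DataFrame, AgentState]:
    """Simulate one agent through a session, sampling every probe choice.

    Returns one record per probe (chronological order) with the probe
    description, the model's choice probability, the sampled choice and
    its accuracy, plus the final agent state.
    """
    values, state = probe_values(model_spec, params, protocol, n_restarts)
    probes = protocol.all_probes()
    assert len(probes) == len(values)
    u = rng.random(len(values))
    correct = u < values["p_correct"].to_numpy()
    records = values.copy()
    records["cue"] = [
        q.cue.label(protocol.phase(q.phase).f1, protocol.phase(q.phase).f2)
        for q in probes
    ]
    records["option_correct"] = [
        q.option_correct.label(
            protocol.phase(q.phase).f1, protocol.phase(q.phase).f2
        )
        for q in probes
    ]
    records["option_lure"] = [
        q.option_lure.label(
            protocol.phase(q.phase).f1, protocol.phase(q.phase).f2
        )
        for q in probes
    ]
    records["chosen"] = np.where(correct, "correct", "lure")
    records["accuracy"] = correct.astype(int)
    return records, state
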