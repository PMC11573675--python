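"""Compiled replay kernels shared by agent simulation and likelihood fitting.

A :class:`ReplayPlan` flattens one subject's protocol into integer arrays:
the observation stream of each phase (compound indices and feature-index
pairs), which consecutive pairs are learnable transitions, and the probe
schedule (cue/option indices, probe positions in the stream). The numba
kernels below deterministically replay temporal-difference successor
updates through those arrays and emit, for every probe, the values of the
correct option and the lure. Both the generative agents and the
likelihood replay call the same kernels, so simulated choice
probabilities and fitted likelihoods agree by construction.

Conventions: successor matrices are identity-initialized and
self-inclusive (the current state counts in its own expected occupancy),
so every entry stays in ``[0, 1/(1-gamma)]``. Feature updates bootstrap
on the *mean* of the two successor-feature rows, which preserves that
bound. The transfer model's permutation mapping is recomputed from the
current transfer matrix once per trial (the matrix does not change
between the two probes of a trial) by best-improvement pairwise-swap
hill climbing from seeded restart permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .task_graphs import TaskProtocol

N_FEATURES = 10
_MAPPING_STREAM = 0x5C1  # seed-sequence tag for mapping restart draws


# ---------------------------------------------------------------------------
# permutation mapping: pairwise-swap hill climbing on the QAP objective


@njit(cache=True)
def qap_objective(A: np.ndarray, B: np.ndarray, perm: np.ndarray) -> float:
    """Frobenius inner product <P A P^T, B> for the permutation perm[i]=pi(i)."""
    n = A.shape[0]
    s = 0.0
    for i in range(n):
        pi = perm[i]
        for j in range(n):
            s += A[i, j] * B[pi, perm[j]]
    return s


@njit(cache=True)
def _swap_delta(A, B, perm, u, v):
    n = A.shape[0]
    pu = perm[u]
    pv = perm[v]
    d = 0.0
    for k in range(n):
        if k == u or k == v:
            continue
        pk = perm[k]
        d += (A[u, k] - A[v, k]) * (B[pv, pk] - B[pu, pk])
        d += (A[k, u] - A[k, v]) * (B[pk, pv] - B[pk, pu])
    d += (A[u, v] - A[v, u]) * (B[pv, pu] - B[pu, pv])
    d += (A[u, u] - A[v, v]) * (B[pv, pv] - B[pu, pu])
    return d


@njit(cache=True)
def hill_climb(A, B, perm0):
    """Best-improvement 2-swap ascent from perm0; returns (perm, objective)."""
    perm = perm0.copy()
    f = qap_objective(A, B, perm)
    n = perm.shape[0]
    improved = True
    while improved:
        improved = False
        best_d = 1e-10
        bu = -1
        bv = -1
        for u in range(n - 1):
            for v in range(u + 1, n):
                d = _swap_delta(A, B, perm, u, v)
                if d > best_d:
                    best_d = d
                    bu = u
                    bv = v
        if bu >= 0:
            tmp = perm[bu]
            perm[bu] = perm[bv]
            perm[bv] = tmp
            f += best_d
            improved = True
    return perm, f


@njit(cache=True)
def hill_climb_restarts(A, B, restarts):
    """Hill climb from each row of ``restarts``; ties keep the earliest."""
    best_perm = restarts[0].copy()
    best_f = -1e300
    for r in range(restarts.shape[0]):
        perm, f = hill_climb(A, B, restarts[r])
        if f > best_f + 1e-10:
            best_f = f
            best_perm = perm
    return best_perm, best_f


# ---------------------------------------------------------------------------
# SR replay kernels


@njit(cache=True)
def sr_compound_replay(
    obs, upd, probe_pos, cue, corr, lure, n_states, alpha, gamma
):
    """Replay one phase for the compound model; emit probe option values.

    The matrix row of the predecessor is moved toward
    ``e_s + gamma * M[s_next]`` after each learnable transition; probes
    scheduled at stream position ``t+1`` read the matrix after that
    update.
    """
    M = np.eye(n_states)
    n_probes = probe_pos.shape[0]
    vc = np.empty(n_probes)
    vl = np.empty(n_probes)
    p = 0
    for t in range(obs.shape[0]):
        if t > 0 and upd[t - 1]:
            s = obs[t - 1]
            sn = obs[t]
            for k in range(n_states):
                target = gamma * M[sn, k]
                if k == s:
                    target += 1.0
                M[s, k] += alpha * (target - M[s, k])
        while p < n_probes and probe_pos[p] == t + 1:
            vc[p] = M[cue[p], corr[p]]
            vl[p] = M[cue[p], lure[p]]
            p += 1
    return vc, vl, M


@njit(cache=True)
def sr_feature_replay(
    obs_f, upd, probe_pos, cue_f, corr_f, lure_f, alpha, gamma
):
    """Replay one phase for the feature model (two-hot successor features)."""
    n = N_FEATURES
    M = np.eye(n)
    n_probes = probe_pos.shape[0]
    vc = np.empty(n_probes)
    vl = np.empty(n_probes)
    mbar = np.empty(n)
    p = 0
    for t in range(obs_f.shape[0]):
        if t > 0 and upd[t - 1]:
            i1 = obs_f[t - 1, 0]
            i2 = obs_f[t - 1, 1]
            j1 = obs_f[t, 0]
            j2 = obs_f[t, 1]
            for k in range(n):
                mbar[k] = 0.5 * (M[j1, k] + M[j2, k])
            for k in range(n):
                phi = 1.0 if (k == i1 or k == i2) else 0.0
                target = phi + gamma * mbar[k]
                M[i1, k] += alpha * (target - M[i1, k])
                M[i2, k] += alpha * (target - M[i2, k])
        while p < n_probes and probe_pos[p] == t + 1:
            c1 = cue_f[p, 0]
            c2 = cue_f[p, 1]
            vc[p] = (
                M[c1, corr_f[p, 0]] + M[c1, corr_f[p, 1]]
                + M[c2, corr_f[p, 0]] + M[c2, corr_f[p, 1]]
            )
            vl[p] = (
                M[c1, lure_f[p, 0]] + M[c1, lure_f[p, 1]]
                + M[c2, lure_f[p, 0]] + M[c2, lure_f[p, 1]]
            )
            p += 1
    return vc, vl, M


@njit(cache=True)
def sr_transfer_replay(
    obs_f, upd, probe_pos, probe_trial, cue_f, corr_f, lure_f,
    M_prior, restarts, alpha, gamma,
):
    """Transfer-phase replay for the mapping model.

    Learns a fresh transfer feature matrix with the same update rule as
    the feature model; before each trial's probes, searches for the
    permutation aligning the (final) prior matrix with the current
    transfer matrix. Emits the permuted-prior and transfer-matrix value
    components separately — they depend only on the learning rates, so
    the omega-weighted mixture (and the softmax) can be applied outside
    the kernel.
    """
    n = N_FEATURES
    M = np.eye(n)
    n_probes = probe_pos.shape[0]
    vc_map = np.empty(n_probes)
    vl_map = np.empty(n_probes)
    vc_dir = np.empty(n_probes)
    vl_dir = np.empty(n_probes)
    mbar = np.empty(n)
    inv = np.empty(n, dtype=np.int64)
    last_trial = -1
    last_perm = np.arange(n)
    p = 0
    for t in range(obs_f.shape[0]):
        if t > 0 and upd[t - 1]:
            i1 = obs_f[t - 1, 0]
            i2 = obs_f[t - 1, 1]
            j1 = obs_f[t, 0]
            j2 = obs_f[t, 1]
            for k in range(n):
                mbar[k] = 0.5 * (M[j1, k] + M[j2, k])
            for k in range(n):
                phi = 1.0 if (k == i1 or k == i2) else 0.0
                target = phi + gamma * mbar[k]
                M[i1, k] += alpha * (target - M[i1, k])
                M[i2, k] += alpha * (target - M[i2, k])
        while p < n_probes and probe_pos[p] == t + 1:
            trial = probe_trial[p]
            if trial != last_trial:
                last_perm, _ = hill_climb_restarts(M_prior, M, restarts[trial])
                for i in range(n):
                    inv[last_perm[i]] = i
                last_trial = trial
            vm = 0.0
            wm = 0.0
            vd = 0.0
            wd = 0.0
            for a in range(2):
                ca = cue_f[p, a]
                ia = inv[ca]
                for b in range(2):
                    ob = corr_f[p, b]
                    lb = lure_f[p, b]
                    vm += M_prior[ia, inv[ob]]
                    wm += M_prior[ia, inv[lb]]
                    vd += M[ca, ob]
                    wd += M[ca, lb]
            vc_map[p] = vm
            vl_map[p] = wm
            vc_dir[p] = vd
            vl_dir[p] = wd
            p += 1
    return vc_map, vl_map, vc_dir, vl_dir, M, last_perm


# ---------------------------------------------------------------------------
# plan construction


@dataclass
class PhasePlan:
    """Flattened arrays for one phase of a protocol."""

    obs_c: np.ndarray  # (n_obs,) compound index a*size2 + b
    obs_f: np.ndarray  # (n_obs, 2) feature indices (a, size1 + b)
    upd: np.ndarray  # (n_obs - 1,) uint8, learnable-transition flags
    probe_pos: np.ndarray  # (n_probes,) observation count before the probe
    probe_trial: np.ndarray  # (n_probes,) 0-based trial index
    is_inference: np.ndarray  # (n_probes,) bool
    probed_size: np.ndarray  # (n_probes,)
    cue_c: np.ndarray
    corr_c: np.ndarray
    lure_c: np.ndarray
    cue_f: np.ndarray  # (n_probes, 2)
    corr_f: np.ndarray
    lure_f: np.ndarray
    n_states: int


@dataclass
class ReplayPlan:
    prior: PhasePlan
    transfer: PhasePlan
    seed: int

    @property
    def n_probes(self) -> int:
        return len(self.prior.probe_pos) + len(self.transfer.probe_pos)

    def is_inference(self) -> np.ndarray:
        return np.concatenate(
            [self.prior.is_inference, self.transfer.is_inference]
        )


def _compound_index(s, size2: int) -> int:
    return s.a * size2 + s.b

def _feature_pair(s, size1: int) -> tuple[int, int]:
    return s.a, size1 + s.b


def _phase_plan(protocol: TaskProtocol, phase: str) -> PhasePlan:
    data = protocol.phase(phase)
    size1, size2 = data.f1.size, data.f2.size
    L = protocol.sequence_length
    stream = protocol.observation_stream(phase)
    n_obs = len(stream)
    obs_c = np.array([_compound_index(s, size2) for s in stream], dtype=np.int64)
    obs_f = np.array([_feature_pair(s, size1) for s in stream], dtype=np.int64)

    # within-trial pairs are learnable; the cross-trial rule mirrors
    # TaskProtocol.transition_pairs
    upd = np.zeros(n_obs - 1, dtype=np.uint8)
    for i in range(n_obs - 1):
        if (i + 1) % L != 0:
            upd[i] = 1
    deterministic = data.f1.kind == "cycle" and data.f2.kind == "cycle"
    if deterministic:
        for i in range(L - 1, n_obs - 1, L):
            last = stream[i]
            succ_a = data.f1.successor(last.a)
            succ_b = data.f2.successor(last.b)
            nxt = stream[i + 1]
            if nxt.a == succ_a and nxt.b == succ_b:
                upd[i] = 1

    probes = [q for pair in data.probes for q in pair]
    n_pr = len(probes)
    arr = dict(
        probe_pos=np.empty(n_pr, dtype=np.int64),
        probe_trial=np.empty(n_pr, dtype=np.int64),
        is_inference=np.empty(n_pr, dtype=np.bool_),
        probed_size=np.empty(n_pr, dtype=np.int64),
        cue_c=np.empty(n_pr, dtype=np.int64),
        corr_c=np.empty(n_pr, dtype=np.int64),
        lure_c=np.empty(n_pr, dtype=np.int64),
        cue_f=np.empty((n_pr, 2), dtype=np.int64),
        corr_f=np.empty((n_pr, 2), dtype=np.int64),
        lure_f=np.empty((n_pr, 2), dtype=np.int64),
    )
    for p, q in enumerate(probes):
        arr["probe_pos"][p] = (q.trial + 1) * L
        arr["probe_trial"][p] = q.trial
        arr["is_inference"][p] = q.probe_type == "inference"
        arr["probed_size"][p] = q.probed_size
        arr["cue_c"][p] = _compound_index(q.cue, size2)
        arr["corr_c"][p] = _compound_index(q.option_correct, size2)
        arr["lure_c"][p] = _compound_index(q.option_lure, size2)
        arr["cue_f"][p] = _feature_pair(q.cue, size1)
        arr["corr_f"][p] = _feature_pair(q.option_correct, size1)
        arr["lure_f"][p] = _feature_pair(q.option_lure, size1)
    return PhasePlan(obs_c=obs_c, obs_f=obs_f, upd=upd, n_states=size1 * size2, **arr)


def get_plan(protocol: TaskProtocol) -> ReplayPlan:
    """Build (and cache on the protocol) the flattened replay plan."""
    plan = getattr(protocol, "_replay_plan", None)
    if plan is None:
        plan = ReplayPlan(
            prior=_phase_plan(protocol, "prior"),
            transfer=_phase_plan(protocol, "transfer"),
            seed=protocol.seed,
        )
        protocol._replay_plan = plan
    return plan


def mapping_restarts(
    protocol_seed: int, n_trials: int, n_restarts: int
) -> np.ndarray:
    """Seeded restart permutations, identity first, per transfer trial.

    Deterministic given the protocol seed, so the agent's generative run
    and the likelihood replay search from identical starting points.
    """
    out = np.empty((n_trials, n_restarts, N_FEATURES), dtype=np.int64)
    for trial in range(n_trials):
        rng = np.random.default_rng(
            np.random.SeedSequence((protocol_seed, _MAPPING_STREAM, trial))
        )
        out[trial, 0] = np.arange(N_FEATURES)
        for r in range(1, n_restarts):
            out[trial, r] = rng.permutation(N_FEATURES)
    return out
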