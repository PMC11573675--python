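"""Product-graph sequence-learning task: factors, compounds, sequences, probes.

The task presents sequences of compound stimuli generated by two graph
factors evolving simultaneously, one step per observation: a directed
cycle (deterministic traversal in a fixed order) and/or an undirected
path (reflecting random walk, equal-probability left/right moves at
interior states). Because both factors are bipartite, the compound state
space of ``size1 * size2`` feature pairs splits into two disconnected
components under the joint dynamics; sequences stay inside one of them
(the "experienced" component) and the other is held out for inference
probes.

After every sequence a pair of two-alternative forced-choice probes is
asked: an *experience* probe about a compound from the just-shown
sequence and an *inference* probe about a held-out compound. The two
answer options always share the non-probed factor's feature and differ
only on the probed factor, so each probe tests knowledge of exactly one
factor (of size 4 or size 6).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GraphFactor",
    "CompoundState",
    "ProbeQuestion",
    "TaskProtocol",
    "TaskError",
    "make_factor",
    "product_components",
    "generate_sequence",
    "build_probes",
    "build_protocol",
    "PRIOR_LABELS_4",
    "PRIOR_LABELS_6",
    "TRANSFER_LABELS_4",
    "TRANSFER_LABELS_6",
]

Kind = Literal["cycle", "path"]
Phase = Literal["prior", "transfer"]

#: Display labels mirroring the published stimulus naming: plain letters and
#: digits during initial learning, primed labels for the 10 novel transfer
#: features.
PRIOR_LABELS_4 = ("A", "B", "C", "D")
PRIOR_LABELS_6 = ("1", "2", "3", "4", "5", "6")
TRANSFER_LABELS_4 = ("A'", "B'", "C'", "D'")
TRANSFER_LABELS_6 = ("7'", "8'", "9'", "10'", "11'", "12'")


class TaskError(ValueError):
    """Raised for invalid task-construction inputs."""


@dataclass(frozen=True)
class GraphFactor:
    """One generative subprocess: a directed cycle or an undirected path.

    Parameters
    ----------
    kind:
        ``"cycle"`` for deterministic forward traversal in label order,
        ``"path"`` for a reflecting random walk on a chain.
    size:
        Number of states (>= 3).
    labels:
        Unique display labels, one per state, in traversal order.
    """

    kind: Kind
    size: int
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("cycle", "path"):
            raise TaskError(f"unsupported factor kind: {self.kind!r}")
        if self.size < 3:
            raise TaskError(f"factor size must be >= 3, got {self.size}")
        if len(self.labels) != self.size:
            raise TaskError(
                f"{len(self.labels)} labels for a factor of size {self.size}"
            )
        if len(set(self.labels)) != self.size:
            raise TaskError(f"duplicate labels: {self.labels}")

    @property
    def bipartite(self) -> bool:
        # even cycles and all paths are bipartite
        return self.kind == "path" or self.size % 2 == 0

    def successor(self, pos: int) -> int:
        """Deterministic successor (cycles only)."""
        if self.kind != "cycle":
            raise TaskError("deterministic successor only defined for cycles")
        return (pos + 1) % self.size

    def predecessor(self, pos: int) -> int:
        if self.kind != "cycle":
            raise TaskError("predecessor only defined for cycles")
        return (pos - 1) % self.size

    def neighbors(self, pos: int) -> tuple[int, ...]:
        """States reachable in one step of the generative dynamics."""
        if self.kind == "cycle":
            return (self.successor(pos),)
        return self.adjacent(pos)

    def adjacent(self, pos: int) -> tuple[int, ...]:
        """Undirected graph neighbours (cycles traversable both ways)."""
        if self.kind == "cycle":
            return ((pos - 1) % self.size, (pos + 1) % self.size)
        out = []
        if pos > 0:
            out.append(pos - 1)
        if pos < self.size - 1:
            out.append(pos + 1)
        return tuple(out)

    def step(self, pos: int, rng: np.random.Generator) -> int:
        """Advance one step: cycles deterministically, paths reflectingly."""
        if self.kind == "cycle":
            return self.successor(pos)
        if pos == 0:
            return 1
        if pos == self.size - 1:
            return self.size - 2
        return pos + 1 if rng.random() < 0.5 else pos - 1


@dataclass(frozen=True, order=True)
class CompoundState:
    """A feature pair: position ``a`` in factor 1, position ``b`` in factor 2."""

    a: int
    b: int

    @property
    def component(self) -> int:
        # parity is invariant under simultaneous +-1 moves of both factors
        return (self.a + self.b) % 2

    def label(self, f1: GraphFactor, f2: GraphFactor) -> str:
        return f1.labels[self.a] + f2.labels[self.b]


@dataclass(frozen=True)
class ProbeQuestion:
    """One two-alternative next-compound prediction question."""

    phase: Phase
    trial: int  # 0-based
    probe_type: Literal["experience", "inference"]
    probed_size: int
    cue: CompoundState
    option_correct: CompoundState
    option_lure: CompoundState

    def __post_init__(self) -> None:
        assert self.option_correct != self.option_lure
        assert self.option_correct != self.cue and self.option_lure != self.cue


def make_factor(
    kind: Kind, size: int, labels: Sequence[str], seed: int | None = None
) -> GraphFactor:
    """Construct and validate a graph factor.

    ``seed`` is accepted for interface symmetry with the stochastic
    constructors; factor construction itself is deterministic.
    """
    return GraphFactor(kind=kind, size=int(size), labels=tuple(labels))


def _joint_moves(
    f1: GraphFactor, f2: GraphFactor, s: CompoundState
) -> Iterator[CompoundState]:
    # undirected adjacency: component structure is a property of the
    # product graph, not of the traversal direction
    for na in f1.adjacent(s.a):
        for nb in f2.adjacent(s.b):
            yield CompoundState(na, nb)


def product_components(
    f1: GraphFactor, f2: GraphFactor
) -> list[frozenset[CompoundState]]:
    """Connected components of the compound space under simultaneous stepping.

    Both factors move one edge per time step, so compound edges join
    ``(a, b)`` to every pair of one-step neighbours ``(a', b')``.
    Reachability is computed by brute force over all ``size1 * size2``
    states. Odd cycles are rejected: they would merge the components,
    which is outside the task design.
    """
    for f in (f1, f2):
        if not f.bipartite:
            raise TaskError(
                f"odd {f.kind} of size {f.size} is not bipartite; "
                "components would merge"
            )
    g = nx.Graph()
    states = [
        CompoundState(a, b) for a in range(f1.size) for b in range(f2.size)
    ]
    g.add_nodes_from(states)
    for s in states:
        for t in _joint_moves(f1, f2, s):
            g.add_edge(s, t)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: min(c))


def generate_sequence(
    f1: GraphFactor,
    f2: GraphFactor,
    start: CompoundState,
    length: int,
    rng: np.random.Generator,
) -> list[CompoundState]:
    """Generate one stimulus sequence by simultaneous factor traversal.

    Cycle factors advance deterministically in their fixed order; path
    factors take a reflecting random walk. The output has ``length``
    compound states beginning with ``start`` and never leaves the
    start's component.
    """
    if not (0 <= start.a < f1.size and 0 <= start.b < f2.size):
        raise TaskError(f"start state {start} outside the state space")
    if length < 1:
        raise TaskError("sequence length must be >= 1")
    seq = [start]
    for _ in range(length - 1):
        prev = seq[-1]
        seq.append(CompoundState(f1.step(prev.a, rng), f2.step(prev.b, rng)))
    return seq


def _probed_factor(f1: GraphFactor, f2: GraphFactor, probed_size: int):
    if probed_size == f1.size:
        return 0, f1
    if probed_size == f2.size:
        return 1, f2
    raise TaskError(f"no factor of probed size {probed_size}")


def _lure_position(
    factor: GraphFactor,
    cue_pos: int,
    correct_pos: int,
    rng: np.random.Generator,
) -> int:
    """Lure feature on the probed factor.

    Cycle: the cue's predecessor (the printed example ``D'8' -> A'9'`` vs
    ``C'9'`` pins this down). Path: a seeded uniform draw over positions
    at distance >= 2 from the cue, which can never be a one-step
    successor of the cue.
    """
    if factor.kind == "cycle":
        lure = factor.predecessor(cue_pos)
    else:
        candidates = [
            q for q in range(factor.size) if abs(q - cue_pos) >= 2
        ]
        assert candidates, "no valid path lure; cannot occur for sizes >= 4"
        lure = int(rng.choice(candidates))
    assert lure != correct_pos and lure != cue_pos
    return lure


def _advance(
    f1: GraphFactor, f2: GraphFactor, s: CompoundState, rng: np.random.Generator
) -> CompoundState:
    return CompoundState(f1.step(s.a, rng), f2.step(s.b, rng))


def _make_probe(
    f1: GraphFactor,
    f2: GraphFactor,
    phase: Phase,
    trial: int,
    probe_type: Literal["experience", "inference"],
    probed_size: int,
    cue: CompoundState,
    nxt: CompoundState,
    rng: np.random.Generator,
) -> ProbeQuestion:
    axis, factor = _probed_factor(f1, f2, probed_size)
    cue_pos = cue.a if axis == 0 else cue.b
    correct_pos = nxt.a if axis == 0 else nxt.b
    lure_pos = _lure_position(factor, cue_pos, correct_pos, rng)
    if axis == 0:
        lure = CompoundState(lure_pos, nxt.b)
    else:
        lure = CompoundState(nxt.a, lure_pos)
    return ProbeQuestion(
        phase=phase,
        trial=trial,
        probe_type=probe_type,
        probed_size=probed_size,
        cue=cue,
        option_correct=nxt,
        option_lure=lure,
    )


def build_probes(
    f1: GraphFactor,
    f2: GraphFactor,
    sequence: Sequence[CompoundState],
    factor_assignment: dict[CompoundState, int],
    phase: Phase,
    trial: int,
    rng: np.random.Generator,
    experience_size: int,
    inference_size: int,
    held_out: Sequence[CompoundState],
) -> tuple[ProbeQuestion, ProbeQuestion]:
    """Build the (experience, inference) probe pair for one trial.

    The experience cue is drawn from the just-shown sequence among
    occurrences assigned to ``experience_size`` (falling back to the
    other size if none is present); its correct option is the transition
    realized in that sequence. The inference cue is drawn from the
    held-out component among compounds assigned to ``inference_size``;
    its correct option is a fresh draw from the generative dynamics.
    """
    # experience probe: cue occurrence must have a realized successor
    sizes = (experience_size, 10 - experience_size)
    for size in sizes:
        eligible = [
            t
            for t in range(len(sequence) - 1)
            if factor_assignment[sequence[t]] == size
        ]
        if eligible:
            exp_size = size
            break
    else:  # pragma: no cover - every compound is assigned a size
        raise TaskError("no eligible experience cue in sequence")
    t = int(rng.choice(eligible))
    exp = _make_probe(
        f1, f2, phase, trial, "experience", exp_size,
        sequence[t], sequence[t + 1], rng,
    )

    inf_candidates = [
        s for s in held_out if factor_assignment[s] == inference_size
    ]
    cue = inf_candidates[int(rng.integers(len(inf_candidates)))]
    inf = _make_probe(
        f1, f2, phase, trial, "inference", inference_size,
        cue, _advance(f1, f2, cue, rng), rng,
    )
    return exp, inf


@dataclass
class PhaseData:
    """Sequences, probes and probed-size assignment for one task phase."""

    f1: GraphFactor
    f2: GraphFactor
    sequences: list[list[CompoundState]]
    probes: list[tuple[ProbeQuestion, ProbeQuestion]]
    assignment: dict[CompoundState, int]
    experienced: tuple[CompoundState, ...]
    held_out: tuple[CompoundState, ...]


@dataclass
class TaskProtocol:
    """Full specification of one subject's session, reproducible from seed."""

    condition: str
    seed: int
    prior: PhaseData
    transfer: PhaseData
    n_prior_trials: int = 48
    n_transfer_trials: int = 36
    sequence_length: int = 12
    experienced_component: int = 0

    def phase(self, phase: Phase) -> PhaseData:
        return self.prior if phase == "prior" else self.transfer

    def observation_stream(self, phase: Phase) -> list[CompoundState]:
        """All observations of a phase, trials concatenated in order."""
        return [s for seq in self.phase(phase).sequences for s in seq]

    def transition_pairs(
        self, phase: Phase
    ) -> list[tuple[CompoundState, CompoundState]]:
        """Ordered compound transitions presented during a phase.

        Within-trial consecutive pairs always count. A pair spanning two
        consecutive trials counts only when the dynamics are fully
        deterministic (both factors cyclic) and the next trial starts at
        the deterministic successor of the previous trial's last state
        (the repeated transfer sequence forms an unbroken walk); a
        restart elsewhere is a teleport, not a transition.
        """
        data = self.phase(phase)
        pairs: list[tuple[CompoundState, CompoundState]] = []
        deterministic = data.f1.kind == "cycle" and data.f2.kind == "cycle"
        for i, seq in enumerate(data.sequences):
            pairs.extend(zip(seq[:-1], seq[1:]))
            if deterministic and i + 1 < len(data.sequences):
                last = seq[-1]
                succ = CompoundState(
                    data.f1.successor(last.a), data.f2.successor(last.b)
                )
                if data.sequences[i + 1][0] == succ:
                    pairs.append((last, succ))
        return pairs

    def all_probes(self) -> list[ProbeQuestion]:
        """Every probe of the session in chronological order."""
        out: list[ProbeQuestion] = []
        for phase in ("prior", "transfer"):
            for exp, inf in self.phase(phase).probes:
                out.extend((exp, inf))
        return out


def _balanced_assignment(
    components: Sequence[frozenset[CompoundState]],
    sizes: tuple[int, int],
    rng: np.random.Generator,
) -> dict[CompoundState, int]:
    """Assign each compound to exactly one probed size, balanced per component."""
    assignment: dict[CompoundState, int] = {}
    for comp in components:
        states = sorted(comp)
        perm = rng.permutation(len(states))
        half = len(states) // 2
        for rank, idx in enumerate(perm):
            assignment[states[idx]] = sizes[0] if rank < half else sizes[1]
    return assignment


def _phase_factors(condition: str, phase: Phase) -> tuple[GraphFactor, GraphFactor]:
    if phase == "transfer":
        return (
            make_factor("cycle", 4, TRANSFER_LABELS_4),
            make_factor("cycle", 6, TRANSFER_LABELS_6),
        )
    if condition == "prior4cycle":
        return (
            make_factor("cycle", 4, PRIOR_LABELS_4),
            make_factor("path", 6, PRIOR_LABELS_6),
        )
    if condition == "prior6cycle":
        return (
            make_factor("path", 4, PRIOR_LABELS_4),
            make_factor("cycle", 6, PRIOR_LABELS_6),
        )
    raise TaskError(f"unknown condition: {condition!r}")


def _build_phase(
    condition: str,
    phase: Phase,
    n_trials: int,
    sequence_length: int,
    experienced_component: int,
    start: CompoundState,
    seed_seq: np.random.SeedSequence,
    factors: tuple[GraphFactor, GraphFactor] | None = None,
) -> PhaseData:
    f1, f2 = factors if factors is not None else _phase_factors(condition, phase)
    rng_assign, rng_seq, rng_probe = (
        np.random.default_rng(s) for s in seed_seq.spawn(3)
    )
    comps = product_components(f1, f2)
    by_id = {min(c).component: c for c in comps}
    experienced = tuple(sorted(by_id[experienced_component]))
    held_out = tuple(sorted(by_id[1 - experienced_component]))
    assignment = _balanced_assignment(comps, (f1.size, f2.size), rng_assign)

    sequences: list[list[CompoundState]] = []
    for _ in range(n_trials):
        if phase == "transfer":
            s0 = start
        else:
            s0 = experienced[int(rng_seq.integers(len(experienced)))]
        sequences.append(generate_sequence(f1, f2, s0, sequence_length, rng_seq))

    # alternate probed sizes so each size is probed equally often per
    # probe type; track counts so a fallback (cue of the scheduled size
    # absent from a stochastic sequence) is compensated later
    probes: list[tuple[ProbeQuestion, ProbeQuestion]] = []
    exp_counts = {f1.size: 0, f2.size: 0}
    for i, seq in enumerate(sequences):
        tie_break = f1.size if i % 2 == 0 else f2.size
        exp_target = min(
            exp_counts, key=lambda s: (exp_counts[s], s != tie_break)
        )
        inf_target = f2.size if i % 2 == 0 else f1.size
        exp, inf = build_probes(
            f1, f2, seq, assignment, phase, i, rng_probe,
            experience_size=exp_target, inference_size=inf_target,
            held_out=held_out,
        )
        exp_counts[exp.probed_size] += 1
        probes.append((exp, inf))
    return PhaseData(
        f1=f1, f2=f2, sequences=sequences, probes=probes,
        assignment=assignment, experienced=experienced, held_out=held_out,
    )


def build_protocol(
    condition: str,
    seed: int,
    n_prior_trials: int = 48,
    n_transfer_trials: int = 36,
    sequence_length: int = 12,
    start: CompoundState = CompoundState(0, 0),
) -> TaskProtocol:
    """Build a full reproducible session for one subject.

    Prior factors are (4-cycle, 6-path) in the ``prior4cycle`` condition
    and (4-path, 6-cycle) in ``prior6cycle``; transfer factors are
    always (4-cycle, 6-cycle) with 10 fresh feature labels. Prior
    sequences restart at a uniformly drawn experienced-component state
    each trial; the transfer sequence starts at ``start`` every trial
    and therefore repeats identically.
    """
    if condition not in ("prior4cycle", "prior6cycle"):
        raise TaskError(f"unknown condition: {condition!r}")
    root = np.random.SeedSequence(seed)
    prior_ss, transfer_ss = root.spawn(2)
    experienced_component = start.component
    prior = _build_phase(
        condition, "prior", n_prior_trials, sequence_length,
        experienced_component, start, prior_ss,
    )
    transfer = _build_phase(
        condition, "transfer", n_transfer_trials, sequence_length,
        experienced_component, start, transfer_ss,
    )
    return TaskProtocol(
        condition=condition,
        seed=seed,
        prior=prior,
        transfer=transfer,
        n_prior_trials=n_prior_trials,
        n_transfer_trials=n_transfer_trials,
        sequence_length=sequence_length,
        experienced_component=experienced_component,
    )
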