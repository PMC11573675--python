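"""Task construction: factors, product components, sequences, probes."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srcompose.task_graphs import (
    CompoundState,
    TaskError,
    _make_probe,
    build_protocol,
    generate_sequence,
    make_factor,
    product_components,
)


def brute_force_components(f1, f2):
    """Independent reachability oracle: BFS over simultaneous moves."""
    states = [(a, b) for a in range(f1.size) for b in range(f2.size)]

    def neighbors(pos, f):
        if f.kind == "cycle":
            return [(pos + 1) % f.size, (pos - 1) % f.size]
        out = []
        if pos > 0:
            out.append(pos - 1)
        if pos < f.size - 1:
            out.append(pos + 1)
        return out

    seen = set()
    comps = []
    for s0 in states:
        if s0 in seen:
            continue
        comp = {s0}
        frontier = [s0]
        while frontier:
            a, b = frontier.pop()
            for na in neighbors(a, f1):
                for nb in neighbors(b, f2):
                    if (na, nb) not in comp:
                        comp.add((na, nb))
                        frontier.append((na, nb))
        seen |= comp
        comps.append(comp)
    return sorted(len(c) for c in comps)


class TestFactors:
    def test_cycle_successor_wraps(self):
        f = make_factor("cycle", 4, ["A", "B", "C", "D"])
        assert f.successor(3) == 0  # D -> A
        assert f.predecessor(3) == 2  # lure direction: D -> C
        f3 = make_factor("cycle", 3, ["x", "y", "z"])
        assert f3.successor(2) == 0

    def test_path_boundary_has_one_neighbor(self):
        f = make_factor("path", 6, list("123456"))
        assert f.neighbors(0) == (1,)
        assert f.neighbors(5) == (4,)
        assert f.neighbors(2) == (1, 3)

    @pytest.mark.parametrize(
        "kind,size,labels",
        [
            ("cycle", 4, ["A", "A", "B", "C"]),  # duplicate labels
            ("ring", 4, ["A", "B", "C", "D"]),  # unsupported kind
            ("cycle", 5, ["A", "B", "C", "D"]),  # size mismatch
            ("cycle", 2, ["A", "B"]),  # too small
        ],
    )
    def test_validation_errors(self, kind, size, labels):
        with pytest.raises(TaskError):
            make_factor(kind, size, labels)


class TestProductComponents:
    @pytest.mark.parametrize(
        "spec1,spec2,expected",
        [
            (("cycle", 4), ("cycle", 6), [12, 12]),
            (("cycle", 4), ("path", 6), [12, 12]),
            (("cycle", 4), ("cycle", 4), [8, 8]),
            (("path", 4), ("cycle", 6), [12, 12]),
            (("path", 5), ("path", 3), [7, 8]),
        ],
    )
    def test_matches_brute_force_oracle(self, spec1, spec2, expected):
        f1 = make_factor(spec1[0], spec1[1], [f"a{i}" for i in range(spec1[1])])
        f2 = make_factor(spec2[0], spec2[1], [f"b{i}" for i in range(spec2[1])])
        comps = product_components(f1, f2)
        sizes = sorted(len(c) for c in comps)
        assert sizes == expected
        assert sizes == brute_force_components(f1, f2)

    def test_odd_cycle_rejected(self):
        f1 = make_factor("cycle", 3, list("xyz"))
        f2 = make_factor("cycle", 6, list("123456"))
        with pytest.raises(TaskError, match="bipartite"):
            product_components(f1, f2)

    def test_even_bipartite_factors_split_in_half(self):
        # 2 components of m*n/2 each, for several even-bipartite pairs
        for m, n in [(4, 6), (6, 6), (4, 4), (6, 4)]:
            f1 = make_factor("cycle", m, [f"a{i}" for i in range(m)])
            f2 = make_factor("path", n, [f"b{i}" for i in range(n)])
            comps = product_components(f1, f2)
            assert [len(c) for c in comps] == [m * n // 2, m * n // 2]


class TestSequences:
    def test_joint_cycle_orbit_covers_component(self, transfer_factors, rng):
        f4, f6 = transfer_factors
        seq = generate_sequence(f4, f6, CompoundState(0, 0), 12, rng)
        assert len(set(seq)) == 12
        assert all(s.component == 0 for s in seq)
        last = seq[-1]
        wrap = CompoundState(f4.successor(last.a), f6.successor(last.b))
        assert wrap == seq[0]  # period lcm(4,6) = 12

    def test_reflecting_boundary_moves_inward(self, rng):
        f4 = make_factor("cycle", 4, list("ABCD"))
        p6 = make_factor("path", 6, list("123456"))
        seq = generate_sequence(f4, p6, CompoundState(0, 0), 2, rng)
        assert seq[1].b == 1

    def test_fixed_seed_reproducible(self, transfer_factors):
        f4 = make_factor("cycle", 4, list("ABCD"))
        p6 = make_factor("path", 6, list("123456"))
        s1 = generate_sequence(f4, p6, CompoundState(1, 1), 12, np.random.default_rng(5))
        s2 = generate_sequence(f4, p6, CompoundState(1, 1), 12, np.random.default_rng(5))
        assert s1 == s2

    def test_start_outside_state_space_rejected(self, transfer_factors, rng):
        f4, f6 = transfer_factors
        with pytest.raises(TaskError):
            generate_sequence(f4, f6, CompoundState(4, 0), 12, rng)

    @settings(max_examples=40, deadline=None)
    @given(
        kind1=st.sampled_from(["cycle", "path"]),
        kind2=st.sampled_from(["cycle", "path"]),
        a0=st.integers(0, 3),
        b0=st.integers(0, 5),
        seed=st.integers(0, 10_000),
    )
    def test_sequences_never_leave_their_component(self, kind1, kind2, a0, b0, seed):
        f1 = make_factor(kind1, 4, [f"a{i}" for i in range(4)])
        f2 = make_factor(kind2, 6, [f"b{i}" for i in range(6)])
        seq = generate_sequence(
            f1, f2, CompoundState(a0, b0), 12, np.random.default_rng(seed)
        )
        assert len({s.component for s in seq}) == 1


class TestProbes:
    def test_published_probe_example(self, transfer_factors, rng):
        # cue D'8' probed on the 4-cycle: next is A'9', lure is C'9'
        f4, f6 = transfer_factors
        cue = CompoundState(3, 1)  # D'8'
        nxt = CompoundState(0, 2)  # A'9'
        probe = _make_probe(f4, f6, "transfer", 0, "experience", 4, cue, nxt, rng)
        assert probe.option_correct.label(f4, f6) == "A'9'"
        assert probe.option_lure.label(f4, f6) == "C'9'"

    def test_options_share_only_the_nonprobed_feature(self, protocol4):
        for q in protocol4.all_probes():
            data = protocol4.phase(q.phase)
            probed_axis = 0 if q.probed_size == data.f1.size else 1
            c, l = q.option_correct, q.option_lure
            if probed_axis == 0:
                assert c.b == l.b and c.a != l.a
            else:
                assert c.a == l.a and c.b != l.b
            assert q.option_correct != q.option_lure
            assert q.cue not in (q.option_correct, q.option_lure)

    def test_probe_cue_components(self, protocol4):
        for q in protocol4.all_probes():
            data = protocol4.phase(q.phase)
            if q.probe_type == "experience":
                assert q.cue in data.experienced
            else:
                assert q.cue in data.held_out

    def test_each_size_probed_equally_often(self, protocol4, protocol6):
        for protocol in (protocol4, protocol6):
            for phase, n in (("prior", 48), ("transfer", 36)):
                probes = protocol.phase(phase).probes
                for idx in (0, 1):  # experience, inference
                    counts = Counter(pair[idx].probed_size for pair in probes)
                    assert counts[4] == counts[6] == n // 2

    def test_experience_cue_comes_from_shown_sequence(self, protocol4):
        for phase in ("prior", "transfer"):
            data = protocol4.phase(phase)
            for seq, (exp, _) in zip(data.sequences, data.probes):
                assert exp.cue in seq[:-1]


class TestProtocol:
    def test_trial_counts_and_factor_kinds(self, protocol4, protocol6):
        for protocol in (protocol4, protocol6):
            assert len(protocol.prior.sequences) == 48
            assert len(protocol.transfer.sequences) == 36
            assert all(len(s) == 12 for s in protocol.prior.sequences)
            assert protocol.transfer.f1.kind == protocol.transfer.f2.kind == "cycle"
        assert protocol4.prior.f1.kind == "cycle" and protocol4.prior.f2.kind == "path"
        assert protocol6.prior.f1.kind == "path" and protocol6.prior.f2.kind == "cycle"

    def test_transfer_sequence_repeats_identically(self, protocol4):
        first = protocol4.transfer.sequences[0]
        assert all(seq == first for seq in protocol4.transfer.sequences)

    def test_prior_and_transfer_labels_disjoint(self, protocol4):
        prior = set(protocol4.prior.f1.labels) | set(protocol4.prior.f2.labels)
        transfer = set(protocol4.transfer.f1.labels) | set(protocol4.transfer.f2.labels)
        assert prior.isdisjoint(transfer)
        assert len(transfer) == 10

    def test_same_seed_identical_protocols(self):
        p1 = build_protocol("prior6cycle", seed=77)
        p2 = build_protocol("prior6cycle", seed=77)
        assert p1.prior.sequences == p2.prior.sequences
        assert p1.prior.probes == p2.prior.probes
        assert p1.transfer.probes == p2.transfer.probes

    def test_unknown_condition_rejected(self):
        with pytest.raises(TaskError):
            build_protocol("prior5cycle", seed=1)

    def test_transfer_transitions_half_of_full_set(self, protocol4, transfer_factors):
        observed = set(protocol4.transition_pairs("transfer"))
        assert len(observed) == 12
        f4, f6 = transfer_factors
        full = {
            (CompoundState(a, b), CompoundState(f4.successor(a), f6.successor(b)))
            for a in range(4)
            for b in range(6)
        }
        assert len(full) == 24
        assert observed < full

    def test_every_sequence_stays_in_one_component(self, protocol4, protocol6):
        for protocol in (protocol4, protocol6):
            for phase in ("prior", "transfer"):
                for seq in protocol.phase(phase).sequences:
                    comps = {s.component for s in seq}
                    assert comps == {protocol.experienced_component}
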