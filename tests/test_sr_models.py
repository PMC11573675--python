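"""Successor agents: update rules, choice rule, mapping search, simulation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import quadratic_assignment

from srcompose.sr_models import (
    GAMMA_DEFAULT,
    ModelError,
    Params,
    SRMatrix,
    apply_mapping,
    choice_prob,
    combine_sr,
    find_mapping,
    option_value,
    probe_probabilities,
    probe_values,
    run_agent,
    update_compound_sr,
    update_feature_sr,
)
from srcompose.synthetic_data import simulate_cohort, uniform_sampler
from srcompose.task_graphs import build_protocol


def qap_value(A, B, perm):
    """Independent objective oracle: plain-python Frobenius inner product."""
    n = len(perm)
    return sum(A[i, j] * B[perm[i], perm[j]] for i in range(n) for j in range(n))


def brute_force_best(A, B):
    best = -np.inf
    for perm in itertools.permutations(range(A.shape[0])):
        best = max(best, qap_value(A, B, perm))
    return best


class TestCompoundUpdate:
    def test_zero_learning_rate_is_identity_operation(self):
        M = SRMatrix.identity(list("abcd"))
        out = update_compound_sr(M, "a", "b", alpha=0.0, gamma=0.9)
        np.testing.assert_array_equal(out.values, np.eye(4))

    def test_single_update_from_identity(self):
        M = SRMatrix.identity(list("abcd"))
        out = update_compound_sr(M, "a", "b", alpha=1.0, gamma=0.9)
        assert out.values[0, 0] == pytest.approx(1.0)
        assert out.values[0, 1] == pytest.approx(0.9)
        # other rows untouched
        np.testing.assert_array_equal(out.values[1:], np.eye(4)[1:])

    def test_unknown_state_rejected(self):
        M = SRMatrix.identity(list("abcd"))
        with pytest.raises(ModelError):
            update_compound_sr(M, "z", "b", 0.5, 0.9)

    def test_36_lap_matrix_equals_truncated_geometric_series(self, protocol4):
        """alpha=1 on the deterministic 12-loop: each entry is the partial
        sum of the discounted-occupancy series, truncated at the number of
        completed laps (information flows one step back per update)."""
        params = Params(1.0, 1.0, 0.3, 0.3)
        _, state = probe_values("M1", params, protocol4)
        M = state.sr_transfer.values
        g = GAMMA_DEFAULT
        stream = [
            s.a * 6 + s.b for s in protocol4.observation_stream("transfer")
        ]
        i0 = stream[0]
        # diagonal of the starting state: laps 0..3 have propagated back
        assert M[i0, i0] == pytest.approx(sum(g ** (12 * j) for j in range(4)), abs=1e-12)

    def test_sr_converges_to_matrix_inverse_oracle(self):
        """With enough laps the learned SR matches (I - gamma T)^-1 rows."""
        protocol = build_protocol("prior4cycle", seed=3, n_transfer_trials=150)
        params = Params(1.0, 1.0, 0.3, 0.3)
        _, state = probe_values("M1", params, protocol)
        M = state.sr_transfer.values
        T = np.zeros((24, 24))
        for a in range(4):
            for b in range(6):
                T[a * 6 + b, ((a + 1) % 4) * 6 + (b + 1) % 6] = 1.0
        oracle = np.linalg.inv(np.eye(24) - GAMMA_DEFAULT * T)
        experienced = [s.a * 6 + s.b for s in protocol.transfer.experienced]
        assert np.abs(M[experienced] - oracle[experienced]).max() < 1e-6

    @settings(max_examples=30, deadline=None)
    @given(
        seed=st.integers(0, 1000),
        alpha=st.floats(0.01, 1.0),
        n_updates=st.integers(1, 60),
    )
    def test_entries_bounded_by_discount_sum(self, seed, alpha, n_updates):
        rng = np.random.default_rng(seed)
        M = SRMatrix.identity(list("abcdef"))
        bound = 1.0 / (1.0 - GAMMA_DEFAULT)
        for _ in range(n_updates):
            s, s_next = rng.integers(0, 6, size=2)
            M = update_compound_sr(M, int(s), int(s_next), alpha, GAMMA_DEFAULT)
            assert M.values.min() >= 0.0
            assert M.values.max() <= bound + 1e-12


class TestFeatureUpdate:
    def test_single_update_from_identity(self):
        M = SRMatrix.identity(list("icjd"))
        out = update_feature_sr(M, ("i", "c"), ("j", "d"), alpha=1.0, gamma=0.9)
        i = out.loc("i")
        assert out.values[i, out.loc("i")] == pytest.approx(1.0)
        assert out.values[i, out.loc("c")] == pytest.approx(1.0)
        assert out.values[i, out.loc("j")] == pytest.approx(0.45)
        assert out.values[i, out.loc("d")] == pytest.approx(0.45)
        # both observed-feature rows receive the same target
        np.testing.assert_allclose(out.values[i], out.values[out.loc("c")])

    def test_cooccurring_features_gain_positive_association(self):
        M = SRMatrix.identity(list("wxyz"))
        out = update_feature_sr(M, ("w", "x"), ("y", "z"), alpha=0.3, gamma=0.9)
        assert out.values[out.loc("w"), out.loc("x")] > 0
        assert out.values[out.loc("x"), out.loc("w")] > 0

    def test_alpha_zero_unchanged(self):
        M = SRMatrix.identity(list("wxyz"))
        out = update_feature_sr(M, ("w", "x"), ("y", "z"), alpha=0.0, gamma=0.9)
        np.testing.assert_array_equal(out.values, np.eye(4))


class TestOptionValueAndChoice:
    def test_identity_matrix_gives_zero_offdiagonal_value(self):
        M = SRMatrix.identity(list("abcd"))
        assert option_value(M, "a", "b", "M1") == 0.0

    def test_feature_readout_sums_four_entries(self):
        M = SRMatrix(labels=("p", "q"), values=np.ones((2, 2)))
        assert option_value(M, ("p", "q"), ("p", "q"), "M2") == pytest.approx(4.0)

    def test_shared_feature_cancels_in_value_difference(self):
        rng = np.random.default_rng(1)
        M = SRMatrix(labels=tuple("abcdef"), values=rng.random((6, 6)))
        cue = ("a", "b")
        v1 = option_value(M, cue, ("c", "e"), "M2")
        v2 = option_value(M, cue, ("d", "e"), "M2")
        expected = (M.values[0, 2] + M.values[1, 2]) - (
            M.values[0, 3] + M.values[1, 3]
        )
        assert v1 - v2 == pytest.approx(expected)

    def test_equal_values_give_half(self):
        for tau in (0.01, 1.0, 50.0):
            assert choice_prob(1.3, 1.3, tau) == pytest.approx(0.5)

    def test_logistic_closed_form(self):
        assert choice_prob(1.0, 0.0, 1.0) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_argmax_limit_and_tau_validation(self):
        assert choice_prob(1.0, 0.0, 1e-9) == pytest.approx(1.0)
        with pytest.raises(ModelError):
            choice_prob(1.0, 0.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(
        v=st.floats(-5, 5),
        dv=st.floats(0.01, 5),
        shift=st.floats(-10, 10),
        tau=st.floats(0.05, 10),
    )
    def test_monotone_and_shift_invariant(self, v, dv, shift, tau):
        assert choice_prob(v + dv, v, tau) > choice_prob(v, v, tau)
        assert choice_prob(v + dv + shift, v + shift, tau) == pytest.approx(
            choice_prob(v + dv, v, tau)
        )


class TestMapping:
    def test_identical_matrices_return_identity(self, rng):
        A = rng.random((6, 6))
        for method in ("exhaustive", "local_search"):
            res = find_mapping(A, A, method=method, rng=np.random.default_rng(0))
            np.testing.assert_array_equal(res.perm, np.arange(6))

    def test_planted_permutation_recovered_on_7_features(self, rng):
        A = rng.random((7, 7))
        p0 = rng.permutation(7)
        B = apply_mapping(A, p0)
        res = find_mapping(A, B, method="exhaustive")
        assert res.objective == pytest.approx(qap_value(A, B, p0))
        assert res.objective == pytest.approx(brute_force_best(A, B))

    def test_exhaustive_matches_plain_enumeration(self, rng):
        A = rng.random((5, 5))
        B = rng.random((5, 5))
        res = find_mapping(A, B, method="exhaustive")
        assert res.objective == pytest.approx(brute_force_best(A, B))
        assert res.objective == pytest.approx(qap_value(A, B, res.perm))

    def test_objective_invariant_under_joint_relabeling(self, rng):
        A = rng.random((5, 5))
        B = rng.random((5, 5))
        base = find_mapping(A, B, method="exhaustive").objective
        q = rng.permutation(5)
        A2 = apply_mapping(A, q)
        B2 = apply_mapping(B, q)
        assert find_mapping(A2, B2, method="exhaustive").objective == pytest.approx(base)

    def test_scipy_qap_never_beats_exhaustive(self, rng):
        A = rng.random((6, 6))
        B = rng.random((6, 6))
        exact = find_mapping(A, B, method="exhaustive").objective
        res = quadratic_assignment(
            A, B, method="faq",
            options={"maximize": True, "rng": np.random.default_rng(0)},
        )
        assert qap_value(A, B, res.col_ind) <= exact + 1e-9

    def test_rotating_a_circulant_block_mapping_preserves_objective(self):
        # circulant successor structure of a cycle: any rotation of a
        # block-aligned mapping is an equally good maximizer
        C = np.zeros((4, 4))
        for i in range(4):
            C[i, (i + 1) % 4] = 1.0
        base = np.arange(4)
        objs = {qap_value(C, C, (base + r) % 4) for r in range(4)}
        assert len({round(o, 9) for o in objs}) == 1

    def test_size_mismatch_rejected(self, rng):
        with pytest.raises(ModelError):
            find_mapping(rng.random((4, 4)), rng.random((5, 5)))

    def test_block_constrained_search_stays_within_factors(self, rng):
        A = rng.random((7, 7))
        B = rng.random((7, 7))
        for method in ("exhaustive", "local_search"):
            res = find_mapping(
                A, B, method=method, blocks=(3, 4), rng=np.random.default_rng(1)
            )
            assert set(res.perm[:3]) == {0, 1, 2}
            assert set(res.perm[3:]) == {3, 4, 5, 6}
        exact = find_mapping(A, B, method="exhaustive", blocks=(3, 4))
        free = find_mapping(A, B, method="exhaustive")
        assert exact.objective <= free.objective + 1e-12
        local = find_mapping(
            A, B, method="local_search", blocks=(3, 4),
            rng=np.random.default_rng(2),
        )
        assert local.objective <= exact.objective + 1e-9


class TestCombine:
    def test_endpoints_and_midpoint(self):
        A = np.ones((3, 3))
        B = np.zeros((3, 3))
        np.testing.assert_array_equal(combine_sr(A, B, 1.0), A)
        np.testing.assert_array_equal(combine_sr(A, B, 0.0), B)
        np.testing.assert_array_equal(combine_sr(A, B, 0.5), np.full((3, 3), 0.5))

    def test_omega_out_of_range_rejected(self):
        with pytest.raises(ModelError):
            combine_sr(np.ones((2, 2)), np.ones((2, 2)), 1.5)


class TestAgents:
    def test_m1_inference_probes_are_exactly_chance(self, protocol4):
        params = Params(0.7, 0.7, 0.2, 0.2)
        values, _ = probe_values("M1", params, protocol4)
        inf = values[values["probe_type"] == "inference"]
        assert (inf["p_correct"] == 0.5).all()
        assert (inf["v_correct"] == 0.0).all()

    def test_same_seed_identical_choice_records(self, protocol4):
        params = Params(0.3, 0.3, 0.3, 0.3, omega=0.6)
        r1, _ = run_agent("M3", params, protocol4, np.random.default_rng(9))
        r2, _ = run_agent("M3", params, protocol4, np.random.default_rng(9))
        assert r1.equals(r2)

    def test_omega_for_m1_rejected(self, protocol4):
        params = Params(0.3, 0.3, 0.3, 0.3, omega=0.5)
        with pytest.raises(ModelError, match="omega"):
            run_agent("M1", params, protocol4, np.random.default_rng(0))

    def test_m2_transfer_predictions_ignore_prior_learning(self, protocol4):
        # changing prior-phase learning must leave M2 transfer choices intact
        p_lo = Params(0.05, 0.3, 0.3, 0.3)
        p_hi = Params(0.95, 0.3, 0.3, 0.3)
        v_lo, _ = probe_values("M2", p_lo, protocol4)
        v_hi, _ = probe_values("M2", p_hi, protocol4)
        t_lo = v_lo[v_lo["phase"] == "transfer"]["p_correct"].to_numpy()
        t_hi = v_hi[v_hi["phase"] == "transfer"]["p_correct"].to_numpy()
        np.testing.assert_allclose(t_lo, t_hi)

    def test_m3_transfer_advantage_for_consistent_cycle(self):
        """Full prior-knowledge reuse (omega=1) boosts probes of the cycle
        carried over from prior learning above the novel cycle's probes."""
        sampler = uniform_sampler(
            alpha_prior=0.25, alpha_transfer=0.25, tau_exp=0.3, tau_inf=0.3,
            omega=1.0,
        )
        from srcompose.fitting import ModelSpec

        table = simulate_cohort(
            15, ModelSpec("M3", 2, 2), sampler, master_seed=42,
            conditions=("prior4cycle",),
        )
        transfer = table[table["phase"] == "transfer"]
        acc4 = transfer[transfer["probed_size"] == 4]["accuracy"].mean()
        acc6 = transfer[transfer["probed_size"] == 6]["accuracy"].mean()
        assert acc4 > acc6

    def test_probe_probabilities_match_probe_values(self, protocol4):
        params = Params(0.3, 0.2, 0.25, 0.4, omega=0.7)
        values, _ = probe_values("M3", params, protocol4)
        p = probe_probabilities("M3", params, protocol4)
        np.testing.assert_allclose(values["p_correct"].to_numpy(), p)
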