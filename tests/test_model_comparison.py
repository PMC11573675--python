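"""WAIC, Laplace draws, model frequencies, posterior simulation."""

import numpy as np
import pandas as pd
import pytest

from srcompose.fitting import ModelSpec, enumerate_model_space, fit_subject
from srcompose.model_comparison import (
    ComparisonError,
    _gaussian_param_draws,
    aic,
    laplace_draws,
    model_frequencies,
    posterior_simulate,
    waic,
)
from srcompose.synthetic_data import (
    protocol_for_subject,
    simulate_cohort,
    uniform_sampler,
)


class TestWaic:
    def test_constant_half_probability_draws(self):
        draws = np.full((5, 168), np.log(0.5))
        w, lppd, p_w = waic(draws)
        assert p_w == pytest.approx(0.0)
        assert w == pytest.approx(2 * 168 * np.log(2))

    def test_duplicating_draws_changes_nothing(self, rng):
        draws = rng.normal(-0.7, 0.1, size=(40, 20))
        assert waic(np.vstack([draws, draws]))[0] == pytest.approx(waic(draws)[0])

    def test_waic_at_least_minus_two_lppd(self, rng):
        draws = rng.normal(-0.7, 0.3, size=(30, 50))
        w, lppd, p_w = waic(draws)
        assert p_w >= 0
        assert w >= -2 * lppd

    def test_single_draw_rejected(self):
        with pytest.raises(ComparisonError):
            waic(np.full((1, 10), -0.7))

    def test_non_finite_rejected(self):
        draws = np.full((3, 4), -0.5)
        draws[0, 0] = -np.inf
        with pytest.raises(ComparisonError):
            waic(draws)


class TestLaplace:
    def test_draw_spread_shrinks_with_curvature(self):
        # quadratic NLL 0.5 c (x - m)^2: Laplace sd should be 1/sqrt(c)
        bounds = [(-10.0, 10.0)]
        sds = {}
        for c in (1.0, 16.0):
            draws, flags = _gaussian_param_draws(
                lambda x, c=c: 0.5 * c * float((x[0] - 1.0) ** 2),
                np.array([1.0]), bounds, 4000, np.random.default_rng(0),
            )
            assert not flags
            sds[c] = draws.std()
        assert sds[16.0] == pytest.approx(sds[1.0] / 4, rel=0.1)

    def test_flat_curvature_flagged_not_fatal(self):
        draws, flags = _gaussian_param_draws(
            lambda x: 0.0, np.array([0.5]), [(0.0, 1.0)], 50,
            np.random.default_rng(1),
        )
        assert "hessian_jittered" in flags
        assert (draws >= 0).all() and (draws <= 1).all()

    def test_zero_draws_rejected(self, m2_cohort_small):
        sid = m2_cohort_small["subject_id"].unique()[0]
        sub = m2_cohort_small[m2_cohort_small["subject_id"] == sid]
        protocol = protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        fit = fit_subject(ModelSpec("M2", 1, 1), sub, protocol, n_starts=1, seed=0)
        with pytest.raises(ComparisonError):
            laplace_draws(fit, fit.model_spec, sub, protocol, n_draws=0)

    def test_fixed_seed_identical_draws(self, m2_cohort_small):
        sid = m2_cohort_small["subject_id"].unique()[0]
        sub = m2_cohort_small[m2_cohort_small["subject_id"] == sid]
        protocol = protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        fit = fit_subject(ModelSpec("M2", 1, 1), sub, protocol, n_starts=1, seed=0)
        d1, _ = laplace_draws(fit, fit.model_spec, sub, protocol, n_draws=20, seed=7)
        d2, _ = laplace_draws(fit, fit.model_spec, sub, protocol, n_draws=20, seed=7)
        np.testing.assert_array_equal(d1, d2)


class TestFrequenciesAndAic:
    @staticmethod
    def synthetic_report(best_specs):
        rows = []
        for sid, best in enumerate(best_specs):
            for spec in enumerate_model_space():
                rows.append(
                    {
                        "subject_id": f"s{sid}",
                        "spec": spec.name,
                        "model": spec.model,
                        "n_free": spec.n_free,
                        "waic": 100.0 if spec.name == best else 200.0,
                    }
                )
        return pd.DataFrame(rows)

    def test_half_of_subjects_best_fit_gives_fifty_percent(self):
        report = self.synthetic_report(
            ["M3_2a2t", "M3_2a2t", "M1_1a1t", "M2_1a2t"]
        )
        freq, class_freq = model_frequencies(report)
        assert freq["M3_2a2t"] == pytest.approx(0.5)
        assert class_freq["M3"] == pytest.approx(0.5)

    def test_class_aggregate_sums_variants(self):
        report = self.synthetic_report(
            ["M3_2a2t", "M3_1a1t", "M3_1a2t", "M2_1a1t"]
        )
        freq, class_freq = model_frequencies(report)
        assert class_freq["M3"] == pytest.approx(
            freq[["M3_1a1t", "M3_1a2t", "M3_2a1t", "M3_2a2t"]].sum()
        )
        assert freq.sum() == pytest.approx(1.0)

    def test_missing_entries_rejected(self):
        report = self.synthetic_report(["M3_2a2t"]).iloc[:-1]
        with pytest.raises(ComparisonError):
            model_frequencies(report)

    def test_unconstrained_variant_never_fits_worse(self, m2_cohort_small):
        """AIC's likelihood term: the 2a/2t optimum dominates the 1a/1t one
        (checked with the nested optimum supplied as a warm start)."""
        sid = m2_cohort_small["subject_id"].unique()[1]
        sub = m2_cohort_small[m2_cohort_small["subject_id"] == sid]
        protocol = protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        f1 = fit_subject(ModelSpec("M2", 1, 1), sub, protocol, n_starts=2, seed=0)
        p = f1.mle_params
        f2 = fit_subject(
            ModelSpec("M2", 2, 2), sub, protocol, n_starts=2, seed=0,
            extra_starts=[[p.alpha_prior, p.alpha_transfer, p.tau_exp, p.tau_inf]],
        )
        assert f2.nll <= f1.nll + 1e-9
        assert aic(f2) - aic(f1) <= 2 * (f2.model_spec.n_free - f1.model_spec.n_free)


class TestPosteriorSimulation:
    def test_m1_fits_simulate_chance_inference(self):
        sampler = uniform_sampler(
            alpha_prior=(0.1, 0.5), alpha_transfer=(0.1, 0.5),
            tau_exp=(0.1, 0.5), tau_inf=(0.1, 0.5),
        )
        table = simulate_cohort(3, ModelSpec("M1", 2, 2), sampler, master_seed=17)
        fits, protocols = {}, {}
        for sid in table["subject_id"].unique():
            sub = table[table["subject_id"] == sid]
            protocol = protocol_for_subject(
                sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
            )
            fits[sid] = fit_subject(
                ModelSpec("M1", 2, 2), sub, protocol, n_starts=1, seed=0, maxfev=200
            )
            protocols[sid] = protocol
        sim = posterior_simulate(fits, protocols, n_reps=4, seed=3)
        inf = sim.table[sim.table["probe_type"] == "inference"]
        n = len(inf)
        assert abs(inf["accuracy"].mean() - 0.5) < 3 * 0.5 / np.sqrt(n)
        inf_cells = sim.cells[sim.cells["probe_type"] == "inference"]
        assert (abs(inf_cells["mean"] - 0.5) < 0.1).all()

    def test_missing_protocol_rejected(self, m2_cohort_small):
        sid = m2_cohort_small["subject_id"].unique()[0]
        sub = m2_cohort_small[m2_cohort_small["subject_id"] == sid]
        protocol = protocol_for_subject(
            sub["condition"].iloc[0], sub["protocol_seed"].iloc[0]
        )
        fit = fit_subject(ModelSpec("M2", 1, 1), sub, protocol, n_starts=1, seed=0)
        with pytest.raises(ComparisonError):
            posterior_simulate({sid: fit}, {}, n_reps=1, seed=0)
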