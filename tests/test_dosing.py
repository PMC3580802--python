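import math

import numpy as np
import pytest

from ebdose import (
    PatientHistory,
    PopulationModel,
    TherapeuticWindow,
    initial_dose,
    is_omega_optimum,
    max_attainable_probability,
    minimum_samples,
    tdm_update,
    update_dose,
    window_probability,
)
from oracles import best_dose_on_grid, sup_window_probability, window_prob_direct


class TestTherapeuticWindow:
    def test_invariants(self):
        with pytest.raises(ValueError):
            TherapeuticWindow(2.0, 2.0)
        with pytest.raises(ValueError):
            TherapeuticWindow(0.0, 2.0)
        w = TherapeuticWindow(2.0, 8.0)
        assert w.therapeutic_index == 4.0
        assert w.geometric_midpoint == pytest.approx(4.0)
        assert w.l1 < w.geometric_midpoint < w.l2


class TestInitialDose:
    def test_unit_example(self):
        m = PopulationModel(0.0, 0.04, 0.04)
        rec = initial_dose(m, [], TherapeuticWindow(0.5, 2.0))
        assert rec.dose == pytest.approx(1.0)
        assert rec.step == 1

    def test_exponent_example(self):
        m = PopulationModel(0.0, 0.04, 0.04, d=2.0)
        assert initial_dose(m, [], TherapeuticWindow(0.5, 2.0)).dose == pytest.approx(1.0)
        assert initial_dose(m, [], TherapeuticWindow(2.0, 8.0)).dose == pytest.approx(2.0)

    def test_matches_grid_maximizer_of_prior_predictive(self, rng):
        for _ in range(20):
            m = PopulationModel(
                rng.normal(0, 1), rng.uniform(0.01, 0.3), rng.uniform(0.01, 0.3),
                beta=np.array([rng.normal(0, 0.5)]), d=rng.uniform(0.5, 2.0),
                covariate_names=("x",),
            )
            x = [float(rng.normal())]
            l1 = rng.uniform(0.5, 3.0)
            w = TherapeuticWindow(l1, l1 * rng.uniform(1.5, 4.0))
            rec = initial_dose(m, x, w)
            best, _ = best_dose_on_grid(
                m.mu_alpha, m.sigma_alpha2, m.beta[0] * x[0], m.d, m.sigma_eps2,
                w.l1, w.l2,
            )
            assert math.log(rec.dose) == pytest.approx(math.log(best), abs=2e-3)


class TestUpdateDose:
    def test_empty_history_reduces_to_initial(self, model, window):
        rec0 = initial_dose(model, [1.0], window)
        rec1 = update_dose(model, PatientHistory(covariates=[1.0]), window)
        assert rec1.dose == rec0.dose
        assert rec1.step == 1

    def test_shrinkage_bracketing(self, model, window):
        d1 = initial_dose(model, [0.0], window).dose
        y1 = window.geometric_midpoint * 1.8  # above target
        h = PatientHistory(covariates=[0.0], observations=[(d1, y1)])
        rec = update_dose(model, h, window)
        rbar = math.log(y1) - model.d * math.log(d1)
        naive = (window.geometric_midpoint * math.exp(-rbar)) ** (1.0 / model.d)
        lo, hi = sorted((naive, d1))
        assert lo < rec.dose < hi

    def test_on_target_keeps_dose_between(self, model, window):
        d1 = initial_dose(model, [0.0], window).dose
        h = PatientHistory(covariates=[0.0],
                           observations=[(d1, window.geometric_midpoint)])
        rec = update_dose(model, h, window)
        rbar = math.log(window.geometric_midpoint) - math.log(d1)
        naive = window.geometric_midpoint * math.exp(-rbar)
        lo, hi = sorted((naive, d1))
        assert lo <= rec.dose <= hi

    def test_maximizes_posterior_predictive_probability(self, rng):
        for _ in range(20):
            m = PopulationModel(
                rng.normal(0, 1), rng.uniform(0.02, 0.3), rng.uniform(0.02, 0.3),
                d=rng.uniform(0.5, 2.0),
            )
            l1 = rng.uniform(0.5, 3.0)
            w = TherapeuticWindow(l1, l1 * rng.uniform(1.5, 4.0))
            n = int(rng.integers(1, 5))
            obs = [
                (float(np.exp(rng.normal(0, 0.5))), float(np.exp(rng.normal(0.5, 0.5))))
                for _ in range(n)
            ]
            h = PatientHistory(observations=obs)
            rec = update_dose(m, h, w)
            post = rec.posterior
            best, best_p = best_dose_on_grid(
                post.alpha_hat, post.v, 0.0, m.d, m.sigma_eps2, w.l1, w.l2
            )
            assert rec.predicted_window_probability >= best_p - 1e-9
            assert math.log(rec.dose) == pytest.approx(math.log(best), abs=2e-3)


class TestWindowProbability:
    def test_symmetric_equals_max(self, model, window):
        # dose placing the log-response mean at the log-midpoint
        rec = initial_dose(model, [0.0], window)
        p = window_probability(model, model.mu_alpha, 0.0, [0.0], rec.dose, window)
        assert p == pytest.approx(max_attainable_probability(model, window), abs=1e-12)

    def test_degenerate_noise(self):
        m = PopulationModel(0.0, 0.04, 1e-12)
        w = TherapeuticWindow(0.5, 2.0)
        assert window_probability(m, 0.0, 0.0, [], 1.0, w) == pytest.approx(1.0)

    def test_monte_carlo_oracle(self, model, window, rng):
        n = 1_000_000
        alpha, x, dose = 1.2, 1.0, 0.8
        logy = alpha + model.beta[0] * x + model.d * math.log(dose) + rng.normal(
            0.0, model.sigma_eps, n
        )
        y = np.exp(logy)
        freq = np.mean((y > window.l1) & (y < window.l2))
        p = window_probability(model, alpha, 0.0, [x], dose, window)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(freq - p) <= 3 * se

    def test_rejects_bad_inputs(self, model, window):
        with pytest.raises(ValueError):
            window_probability(model, 0.0, 0.0, [0.0], -1.0, window)
        with pytest.raises(ValueError):
            window_probability(model, 0.0, -0.1, [0.0], 1.0, window)


class TestMaxAttainable:
    def test_vanishing_window(self, model):
        w = TherapeuticWindow(1.0, 1.0 * (1 + 1e-12))
        assert max_attainable_probability(model, w) == pytest.approx(0.0, abs=1e-9)

    def test_vanishing_noise(self):
        m = PopulationModel(0.0, 0.04, 1e-16)
        assert max_attainable_probability(m, TherapeuticWindow(1.0, 1.1)) == pytest.approx(1.0)

    def test_closed_form(self, model, window):
        expected = 2 * 0.5 * (
            math.erf(math.log(window.l2 / window.l1) / (2 * model.sigma_eps) / math.sqrt(2))
        ) + 2 * 0.5 - 1.0
        assert max_attainable_probability(model, window) == pytest.approx(expected, abs=1e-12)

    def test_equals_supremum_over_dose(self, rng):
        for _ in range(20):
            m = PopulationModel(
                rng.normal(0, 1), rng.uniform(0.01, 0.3), rng.uniform(0.01, 0.3),
                d=rng.uniform(0.5, 2.0),
            )
            l1 = rng.uniform(0.5, 3.0)
            w = TherapeuticWindow(l1, l1 * rng.uniform(1.2, 5.0))
            sup = sup_window_probability(0.0, m.d, m.sigma_eps2, w.l1, w.l2,
                                         alpha=float(rng.normal()))
            assert max_attainable_probability(m, w) == pytest.approx(sup, abs=1e-6)


class TestOmegaOptimum:
    def test_optimal_dose_is_omega_optimum(self, model, window):
        alpha = 1.3
        dose = (window.geometric_midpoint * math.exp(-alpha)) ** (1.0 / model.d)
        for omega in (0.5, 0.9, 0.99):
            assert is_omega_optimum(dose, alpha, model, [0.0], window, omega)

    def test_tiny_dose_is_not(self, model, window):
        assert not is_omega_optimum(1e-9, 1.0, model, [0.0], window, 0.5)

    def test_bisection_boundary_flips_flag(self, model, window):
        alpha, omega = 1.0, 0.9
        target = omega * max_attainable_probability(model, window)
        opt = window.geometric_midpoint * math.exp(-alpha)

        def p(dose):
            return window_probability(model, alpha, 0.0, [0.0], dose, window)

        lo, hi = opt * 1e-3, opt
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if p(mid) < target:
                lo = mid
            else:
                hi = mid
        boundary = math.sqrt(lo * hi)
        assert not is_omega_optimum(boundary * 0.99, alpha, model, [0.0], window, omega)
        assert is_omega_optimum(boundary * 1.01, alpha, model, [0.0], window, omega)

    def test_invalid_omega(self, model, window):
        with pytest.raises(ValueError):
            is_omega_optimum(1.0, 1.0, model, [0.0], window, 1.0)


class TestTdmUpdate:
    def test_unchanged_at_target(self):
        assert tdm_update(100.0, 4.0, 4.0) == pytest.approx(100.0)

    def test_halves_when_double(self):
        assert tdm_update(100.0, 8.0, 4.0) == pytest.approx(50.0)

    def test_doubles_when_half(self):
        assert tdm_update(100.0, 2.0, 4.0) == pytest.approx(200.0)

    def test_generalized_exponent(self):
        assert tdm_update(100.0, 8.0, 4.0, d=2.0) == pytest.approx(100.0 / math.sqrt(2))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tdm_update(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            tdm_update(1.0, -1.0, 1.0)


class TestMinimumSamples:
    def test_zero_between_variance_needs_no_samples(self, window):
        m = PopulationModel(1.0, 0.0, 0.04)
        assert minimum_samples(m, window, n_sim=2000, seed=1) == 0

    def test_wide_window_needs_no_samples(self):
        m = PopulationModel(1.0, 0.01, 0.01)
        w = TherapeuticWindow(0.01, 10_000.0)
        assert minimum_samples(m, w, n_sim=2000, seed=1) == 0

    def test_deterministic_given_seed(self, model, window):
        a = minimum_samples(model, window, n_sim=4000, seed=11)
        b = minimum_samples(model, window, n_sim=4000, seed=11)
        assert a == b

    def test_sentinel_when_unattainable(self, model):
        # narrow window: even perfect information cannot reach omega fraction
        w = TherapeuticWindow(1.0, 1.0001)
        m = PopulationModel(1.0, 0.09, 0.04)
        out = minimum_samples(m, w, omega=0.999, population_fraction=0.999,
                              max_n=3, n_sim=1000, seed=2)
        assert out == 4

    def test_invalid_fractions(self, model, window):
        with pytest.raises(ValueError):
            minimum_samples(model, window, omega=1.5, seed=0)
        with pytest.raises(ValueError):
            minimum_samples(model, window, population_fraction=0.0, seed=0)


class TestUnitRescaling:
    def test_doses_and_probabilities_invariant(self, model, window):
        c = 12.5
        scaled_model = PopulationModel(
            model.mu_alpha + math.log(c), model.sigma_alpha2, model.sigma_eps2,
            model.beta, model.d, model.covariate_names,
        )
        scaled_window = window.scaled(c)
        r1 = initial_dose(model, [1.0], window)
        r2 = initial_dose(scaled_model, [1.0], scaled_window)
        assert r1.dose == pytest.approx(r2.dose, rel=1e-12)
        p1 = window_probability(model, 1.2, 0.02, [1.0], r1.dose, window)
        p2 = window_probability(scaled_model, 1.2 + math.log(c), 0.02, [1.0],
                                r2.dose, scaled_window)
        assert p1 == pytest.approx(p2, abs=1e-12)
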