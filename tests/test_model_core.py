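"""Closed-form two-compartment model: rates, profiles, exposure integrals."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hs
from scipy.integrate import solve_ivp

from mpapk.model_core import (
    DoseEvent,
    ModelValidationError,
    PKParameters,
    PopulationModel,
    Regimen,
    apply_stage_covariates,
    auc_model_interval,
    conc_profile,
    disposition_rates,
    individual_params,
)

TYPICALS = PKParameters(ka=1.36, V=78.07, V2=554.52, CL=23.36, Q=29.53, Tlag=0.23)


def ode_profile(p, dose, times):
    """Independent oracle: stiff ODE integration of depot/central/peripheral."""
    r = disposition_rates(p)

    def rhs(t, y):
        depot, central, peripheral = y
        return [
            -p.ka * depot,
            p.ka * depot - (r.k10 + r.k12) * central + r.k21 * peripheral,
            r.k12 * central - r.k21 * peripheral,
        ]

    shifted = np.asarray(times) - p.Tlag
    out = np.zeros(shifted.size)
    positive = shifted > 0
    if positive.any():
        sol = solve_ivp(rhs, (0.0, shifted[positive].max()), [dose, 0.0, 0.0],
                        t_eval=shifted[positive], rtol=1e-11, atol=1e-13)
        out[positive] = sol.y[1] / p.V
    return out


class TestDispositionRates:
    def test_symmetric_case_collapses_micro_constants(self):
        p = PKParameters(ka=1.0, V=10.0, V2=10.0, CL=5.0, Q=5.0, Tlag=0.1)
        r = disposition_rates(p)
        assert r.k10 == r.k12 == r.k21 == pytest.approx(0.5)
        assert r.alpha * r.beta == pytest.approx(r.k10 * r.k21, rel=1e-12)
        assert r.alpha + r.beta == pytest.approx(r.k10 + r.k12 + r.k21, rel=1e-12)

    def test_typical_parameters_satisfy_root_identities(self):
        r = disposition_rates(TYPICALS)
        assert r.alpha > r.beta > 0
        assert r.alpha * r.beta == pytest.approx(r.k10 * r.k21, rel=1e-12)

    def test_exponents_match_polynomial_roots(self, rng):
        for _ in range(50):
            p = PKParameters(*np.exp(rng.normal(0.0, 1.0, 6) + np.log(
                [1.4, 80.0, 500.0, 20.0, 30.0, 0.2])))
            r = disposition_rates(p)
            roots = np.roots([1.0, -(r.k10 + r.k12 + r.k21), r.k10 * r.k21])
            assert sorted(roots) == pytest.approx([r.beta, r.alpha], rel=1e-10)

    def test_nonpositive_parameter_rejected(self):
        with pytest.raises(ModelValidationError):
            PKParameters(ka=0.0, V=10, V2=10, CL=5, Q=5, Tlag=0.1)


class TestConcProfile:
    def test_zero_before_lag(self):
        conc = conc_profile(TYPICALS, [DoseEvent(0.0, 1000.0)], [0.0, 0.1, 0.22])
        assert np.all(conc == 0.0)

    def test_matches_ode_oracle_at_typicals(self):
        times = np.linspace(0.3, 12.0, 40)
        closed = conc_profile(TYPICALS, [DoseEvent(0.0, 1000.0)], times)
        ode = ode_profile(TYPICALS, 1000.0, times)
        assert np.max(np.abs(closed - ode) / ode.max()) < 1e-6

    def test_matches_ode_oracle_on_random_parameters(self, rng):
        times = np.linspace(0.1, 24.0, 30)
        for _ in range(12):
            p = PKParameters(*np.exp(rng.normal(0.0, 0.6, 6) + np.log(
                [1.4, 80.0, 500.0, 20.0, 30.0, 0.2])))
            closed = conc_profile(p, [DoseEvent(0.0, 500.0)], times)
            ode = ode_profile(p, 500.0, times)
            assert np.max(np.abs(closed - ode)) / max(ode.max(), 1e-12) < 1e-6

    def test_linear_in_dose(self):
        times = np.linspace(0.0, 12.0, 25)
        c1 = conc_profile(TYPICALS, [DoseEvent(0.0, 500.0)], times)
        c2 = conc_profile(TYPICALS, [DoseEvent(0.0, 1000.0)], times)
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)

    def test_superposition_of_shifted_single_doses(self):
        times = np.linspace(0.0, 48.0, 97)
        doses = [DoseEvent(t, 750.0) for t in (0.0, 12.0, 24.0)]
        multi = conc_profile(TYPICALS, doses, times)
        total = sum(conc_profile(TYPICALS, [d], times) for d in doses)
        assert multi == pytest.approx(total, abs=1e-12)

    def test_continuous_at_lag_time(self):
        eps = 1e-7
        around = conc_profile(TYPICALS, [DoseEvent(0.0, 1000.0)],
                              [TYPICALS.Tlag - eps, TYPICALS.Tlag + eps])
        assert abs(around[1] - around[0]) < 1e-3

    def test_ka_equal_to_hybrid_exponent_is_finite(self):
        r = disposition_rates(TYPICALS)
        p = dataclasses.replace(TYPICALS, ka=r.alpha)
        conc = conc_profile(p, [DoseEvent(0.0, 1000.0)], np.linspace(0.3, 12, 20))
        assert np.all(np.isfinite(conc)) and np.all(conc >= 0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(eta=hs.lists(hs.floats(-1.5, 1.5), min_size=6, max_size=6))
    def test_concentration_never_negative(self, eta):
        p = individual_params(TYPICALS, eta)
        conc = conc_profile(p, [DoseEvent(0.0, 1000.0), DoseEvent(12.0, 1000.0)],
                            np.linspace(0.0, 36.0, 50))
        assert np.all(conc >= 0.0)


class TestAucModelInterval:
    def test_single_dose_total_auc_equals_dose_over_cl(self):
        # 10 terminal half-lives beyond which the remaining area is negligible
        r = disposition_rates(TYPICALS)
        horizon = 10.0 * np.log(2.0) / r.beta
        auc = auc_model_interval(TYPICALS, [DoseEvent(0.0, 1000.0)],
                                 (0.0, horizon), grid_step=0.05)
        assert auc == pytest.approx(1000.0 / TYPICALS.CL, rel=5e-3)

    def test_zero_width_window(self):
        assert auc_model_interval(TYPICALS, Regimen(dose=1000, n_doses=1), (3.0, 3.0)) == 0.0

    def test_reversed_window_rejected(self):
        with pytest.raises(ModelValidationError):
            auc_model_interval(TYPICALS, Regimen(dose=1000, n_doses=1), (5.0, 1.0))

    def test_steady_state_interval_converges_to_dose_over_cl(self):
        # stable-stage typicals have a ~51 h terminal half-life, so true
        # steady state needs ~80 bid doses
        stable = apply_stage_covariates(PopulationModel.renal_transplant(), 1)
        reg = Regimen(dose=500.0, n_doses=80, stage=1)
        auc = auc_model_interval(stable, reg, (79 * 12.0, 80 * 12.0))
        assert auc == pytest.approx(500.0 / stable.CL, rel=1e-3)

    def test_day4_interval_is_below_steady_state(self):
        stable = apply_stage_covariates(PopulationModel.renal_transplant(), 1)
        auc4 = auc_model_interval(stable, Regimen(dose=500.0, n_doses=7), (72.0, 84.0))
        assert auc4 < 500.0 / stable.CL


class TestCovariatesAndRandomEffects:
    def test_stage_zero_returns_typicals(self, final_model):
        p = apply_stage_covariates(final_model, 0)
        assert p.CL == pytest.approx(23.36)
        assert p.V == pytest.approx(78.07)

    def test_stage_one_applies_exponential_coefficients(self, final_model):
        p = apply_stage_covariates(final_model, 1)
        assert p.CL == pytest.approx(23.36 * np.exp(-0.82), rel=1e-12)
        assert p.V == pytest.approx(78.07 * np.exp(-2.54), rel=1e-12)

    def test_zero_coefficients_are_identity(self, final_model):
        neutral = dataclasses.replace(
            final_model,
            covariate_effects=tuple(
                dataclasses.replace(e, coeff=0.0) for e in final_model.covariate_effects
            ),
        )
        assert apply_stage_covariates(neutral, 1) == final_model.theta

    def test_individual_params_identity_and_scaling(self):
        assert individual_params(TYPICALS, np.zeros(6)) == TYPICALS
        eta = np.zeros(6)
        eta[3] = np.log(2.0)  # CL position in canonical order
        doubled = individual_params(TYPICALS, eta)
        assert doubled.CL == pytest.approx(2 * TYPICALS.CL)
        assert doubled.V == TYPICALS.V

    def test_lognormal_eta_variance_recovered(self, rng):
        omega2 = 0.2
        etas = rng.normal(0.0, np.sqrt(omega2), 100_000)
        cls = TYPICALS.CL * np.exp(etas)
        assert np.var(np.log(cls)) == pytest.approx(omega2, rel=0.02)
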