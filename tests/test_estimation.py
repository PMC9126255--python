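"""Mixed-effects estimation: objective, empirical Bayes, selection, bootstrap."""

import dataclasses

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize_scalar

from mpapk import CohortDesign, generate_cohort
from mpapk.data_model import Dataset, Observation, SubjectRecord
from mpapk.estimation import (
    FitOptions,
    bootstrap_fit,
    chi2_threshold,
    empirical_bayes,
    eta_shrinkage,
    fit_population,
    foce_ofv,
    nca_start_model,
    stepwise_covariates,
)
from mpapk.model_core import (
    DoseEvent,
    PKParameters,
    PopulationModel,
    conc_profile,
)

TYPICALS = PKParameters(ka=1.36, V=78.07, V2=554.52, CL=23.36, Q=29.53, Tlag=0.23)

FAST = FitOptions(compute_se=False, multi_start=1, maxiter=20, max_cycles=2,
                  plateau_window=15, cycle_tol=0.2)


def one_eta_toy(seed, omega2=0.1, sigma=0.2):
    """A single-subject dataset with inter-individual variability on CL only."""
    rng = np.random.default_rng(seed)
    model = PopulationModel(theta=TYPICALS, covariate_effects=(),
                            omega2={"CL": omega2}, sigma_prop=sigma)
    eta = rng.normal(0.0, np.sqrt(omega2))
    p = dataclasses.replace(TYPICALS, CL=TYPICALS.CL * np.exp(eta))
    doses = (DoseEvent(0.0, 1000.0),)
    t = np.array([0.5, 1, 2, 3, 4, 6, 8, 12.0])
    f = conc_profile(p, doses, t)
    y = np.maximum(f * (1 + rng.normal(0, sigma, t.size)), 1e-3)
    subject = SubjectRecord("toy", 0, doses,
                            tuple(Observation(float(a), float(b)) for a, b in zip(t, y)),
                            {"STAGE": 0.0})
    return model, Dataset(subjects=(subject,), lloq=1e-6)


def gh_neg2ll(model, data, n_nodes=60):
    """Adaptive Gauss-Hermite oracle for the 1-eta marginal -2 log-likelihood."""
    sub = data.subjects[0]
    t, y, _ = sub.observation_arrays()
    om2 = model.omega2["CL"]
    sig = model.sigma_prop

    def neg2logg(eta):
        p = dataclasses.replace(model.theta, CL=model.theta.CL * np.exp(eta))
        f = np.maximum(conc_profile(p, sub.doses, t), 1e-12)
        var = (sig * f) ** 2
        return float((((y - f) ** 2 / var) + np.log(2 * np.pi * var)).sum()
                     + eta * eta / om2 + np.log(2 * np.pi * om2))

    mode = minimize_scalar(neg2logg, bounds=(-4, 4), method="bounded",
                           options={"xatol": 1e-10}).x
    h = 1e-4
    curv = (neg2logg(mode + h) + neg2logg(mode - h) - 2 * neg2logg(mode)) / h**2
    scale = 1.0 / np.sqrt(max(curv / 2.0, 1e-12))
    x, w = hermgauss(n_nodes)
    vals = np.array([-0.5 * neg2logg(mode + np.sqrt(2) * scale * xi) for xi in x])
    log_lik = np.log(np.sqrt(2) * scale) + np.logaddexp.reduce(np.log(w) + x * x + vals)
    return -2.0 * log_lik


class TestChi2Threshold:
    def test_stepwise_cutoffs(self):
        assert chi2_threshold(0.01, 1) == pytest.approx(6.63, abs=0.005)
        assert chi2_threshold(0.001, 1) == pytest.approx(10.83, abs=0.005)

    def test_limit_alpha_to_one(self):
        assert chi2_threshold(0.9999, 1) == pytest.approx(0.0, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            chi2_threshold(0.0, 1)
        with pytest.raises(ValueError):
            chi2_threshold(0.05, 0)


class TestFoceObjective:
    def test_zero_omega_reduces_to_weighted_least_squares(self, final_model, full_cohort):
        neutral = dataclasses.replace(final_model, covariate_effects=(), omega2={})
        subject = full_cohort.subjects[0]
        data = Dataset(subjects=(subject,), lloq=full_cohort.lloq)
        ofv = foce_ofv(neutral, data)
        t, y, blq = subject.observation_arrays()
        keep = ~blq
        f = np.maximum(conc_profile(neutral.theta, subject.doses, t[keep]), 1e-12)
        var = (neutral.sigma_prop * f) ** 2
        reference = float((((y[keep] - f) ** 2 / var) + np.log(2 * np.pi * var)).sum())
        assert ofv == pytest.approx(reference, abs=1e-6)

    def test_matches_quadrature_oracle_on_one_eta_toys(self):
        for seed in range(10):
            model, data = one_eta_toy(seed)
            assert abs(foce_ofv(model, data) - gh_neg2ll(model, data)) < 0.5

    def test_invariant_to_subject_order(self, small_cohort, final_model):
        reversed_ds = Dataset(subjects=tuple(reversed(small_cohort.subjects)),
                              lloq=small_cohort.lloq)
        a = foce_ofv(final_model, small_cohort)
        b = foce_ofv(final_model, reversed_ds)
        assert a == pytest.approx(b, abs=1e-6)

    def test_worse_model_has_higher_ofv(self, small_cohort, final_model):
        worse = dataclasses.replace(
            final_model,
            theta=dataclasses.replace(final_model.theta, CL=final_model.theta.CL * 3))
        assert foce_ofv(worse, small_cohort) > foce_ofv(final_model, small_cohort)


class TestEmpiricalBayes:
    def test_no_observations_returns_prior_mode(self, final_model):
        subject = SubjectRecord("empty", 0, (DoseEvent(0.0, 1000.0),), (),
                                {"STAGE": 0.0})
        assert empirical_bayes(final_model, subject) == pytest.approx(np.zeros(6))

    def test_one_dimensional_mode_matches_grid_search(self):
        model, data = one_eta_toy(3)
        eta_hat = empirical_bayes(model, data.subjects[0])[3]  # CL position
        sub = data.subjects[0]
        t, y, _ = sub.observation_arrays()

        def neg2logg(eta):
            p = dataclasses.replace(model.theta, CL=model.theta.CL * np.exp(eta))
            f = np.maximum(conc_profile(p, sub.doses, t), 1e-12)
            var = (model.sigma_prop * f) ** 2
            return (((y - f) ** 2 / var) + np.log(2 * np.pi * var)).sum() \
                + eta * eta / model.omega2["CL"]

        grid = np.linspace(-2, 2, 40001)
        oracle = grid[np.argmin([neg2logg(e) for e in grid])]
        assert eta_hat == pytest.approx(oracle, abs=1e-4)

    def test_noise_free_mode_reproduces_profile_and_dominates_truth(self, final_model):
        # a 10-point noise-free profile does not identify all six etas — a
        # (ka, V) combination away from the generating one can fit the curve
        # to sub-percent accuracy at lower prior cost.  What must hold: the
        # mode's predicted profile matches the data to noise level, and its
        # joint density is at least as good as the generating eta's.
        sharp = dataclasses.replace(final_model, covariate_effects=(), sigma_prop=0.01)
        rng = np.random.default_rng(5)
        eta_true = rng.normal(0, 0.3, 6)
        p = PKParameters.from_array(sharp.theta.as_array() * np.exp(eta_true))
        doses = tuple(DoseEvent(12.0 * k, 1000.0) for k in range(7))
        t = 72.0 + np.array([0, 0.5, 1, 1.5, 2, 3, 4, 6, 8, 12.0])
        f = conc_profile(p, doses, t)
        subject = SubjectRecord("nf", 0, doses,
                                tuple(Observation(float(a), float(b)) for a, b in zip(t, f)),
                                {"STAGE": 0.0})
        eta_hat = empirical_bayes(sharp, subject)
        fitted = PKParameters.from_array(sharp.theta.as_array() * np.exp(eta_hat))
        predicted = conc_profile(fitted, doses, t)
        assert predicted == pytest.approx(f, rel=0.02)  # within 2x residual sd

        omega2 = sharp.omega2_array()
        def joint(eta, conc):
            var = (sharp.sigma_prop * conc) ** 2
            return float((((f - conc) ** 2 / var) + np.log(2 * np.pi * var)).sum()
                         + (eta * eta / omega2).sum())

        assert joint(eta_hat, predicted) <= joint(eta_true, f) + 1e-6


class TestEtaShrinkage:
    def test_sd_equal_to_omega_gives_zero(self, rng):
        etas = np.zeros((5000, 6))
        etas[:, 3] = rng.normal(0, np.sqrt(0.2), 5000)
        etas[:, 3] *= np.sqrt(0.2) / etas[:, 3].std(ddof=1)
        out = eta_shrinkage(etas, {"CL": 0.2})
        assert out["CL"] == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_etas_give_full_shrinkage(self):
        assert eta_shrinkage(np.zeros((10, 6)), {"CL": 0.2})["CL"] == pytest.approx(100.0)

    def test_zero_omega_is_undefined(self):
        assert np.isnan(eta_shrinkage(np.zeros((10, 6)), {"CL": 0.0})["CL"])


class TestFitPopulation:
    def test_refit_from_truth_does_not_worsen(self, small_cohort, final_model):
        start_ofv = foce_ofv(final_model, small_cohort)
        fit = fit_population(final_model, small_cohort, FAST)
        assert fit.ofv <= start_ofv + 1e-6

    def test_recovery_under_moderate_variability(self, final_model):
        # with moderate omegas the approximation is accurate and the fitted
        # typicals land near the generating values
        gentle = dataclasses.replace(
            final_model, omega2={k: 0.05 for k in final_model.omega2}, sigma_prop=0.15)
        ds = generate_cohort(gentle, CohortDesign(), seed=11)
        fit = fit_population(nca_start_model(ds),
                             ds, FitOptions(compute_se=False, multi_start=1))
        for name in ("ka", "V", "CL", "Q", "Tlag"):
            est = getattr(fit.model.theta, name)
            true = getattr(gentle.theta, name)
            assert abs(est - true) / true < 0.15, name
        assert fit.model.dCLdStage == pytest.approx(-0.82, abs=0.25)
        assert fit.model.dVdStage == pytest.approx(-2.54, abs=0.4)


class TestStepwise:
    def test_empty_candidate_list_returns_base(self, small_cohort, final_model):
        base = dataclasses.replace(final_model, covariate_effects=())
        model, fit, log = stepwise_covariates(base, [], small_cohort, options=FAST)
        assert model.covariate_effects == ()
        assert log.steps == []

    def test_unknown_candidate_covariate_rejected(self, small_cohort, final_model):
        base = dataclasses.replace(final_model, covariate_effects=())
        with pytest.raises(ValueError, match="NOPE"):
            stepwise_covariates(base, [("NOPE", "CL")], small_cohort, options=FAST)


class TestBootstrap:
    def test_single_subject_replicates_identical(self, final_model, full_cohort):
        data = Dataset(subjects=(full_cohort.subjects[0],), lloq=full_cohort.lloq)
        neutral = dataclasses.replace(final_model, covariate_effects=())
        result = bootstrap_fit(neutral, data, n_resamples=3, seed=1, options=FAST)
        for values in result.estimates.values():
            assert np.ptp(values) == pytest.approx(0.0, abs=1e-9)

    def test_ci_bounds_ordered(self, small_cohort, final_model):
        result = bootstrap_fit(final_model, small_cohort, n_resamples=5, seed=2,
                               options=FAST)
        assert result.n_converged >= 1
        for label, (lo, hi) in result.ci95.items():
            assert lo <= result.medians[label] <= hi
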