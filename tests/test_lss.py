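"""Limited sampling strategies: Bayesian MAP and regression AUC prediction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from mpapk.data_model import Observation, SubjectRecord
from mpapk.lss import (
    SamplingScheme,
    bayesian_lss_auc,
    evaluate_schemes,
    fit_lss_regression,
    prediction_error,
    rmse,
)
from mpapk.model_core import DoseEvent, apply_stage_covariates, conc_profile
from mpapk.nca import trapezoid_auc

DESIGN = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)


class TestErrorMetrics:
    @pytest.mark.parametrize("pred,obs,expected", [
        (50.0, 50.0, 0.0),
        (55.0, 50.0, 10.0),
        (45.0, 50.0, -10.0),
    ])
    def test_prediction_error_arithmetic(self, pred, obs, expected):
        assert prediction_error(pred, obs) == pytest.approx(expected)

    def test_prediction_error_requires_positive_reference(self):
        with pytest.raises(ValueError):
            prediction_error(10.0, 0.0)

    def test_rmse_examples(self):
        assert rmse([10.0, -10.0]) == pytest.approx(10.0)
        assert rmse([0.0, 0.0, 0.0]) == 0.0
        with pytest.raises(ValueError):
            rmse([])

    def test_rmse_matches_direct_formula(self, rng):
        pe = rng.normal(0, 20, 64)
        assert rmse(pe) == pytest.approx(float(np.sqrt((pe**2).mean())), rel=1e-12)


class TestRegression:
    def test_exact_linear_combination_recovered(self, rng):
        c1 = rng.uniform(1, 10, 40)
        c4 = rng.uniform(1, 10, 40)
        frame = pd.DataFrame({1.0: c1, 2.0: rng.uniform(1, 10, 40), 4.0: c4})
        auc = 5.0 + 2.0 * c1 + 3.0 * c4
        formula = fit_lss_regression(auc, frame, SamplingScheme((1.0, 2.0, 4.0)))
        assert formula.intercept == pytest.approx(5.0, abs=1e-8)
        assert formula.coefficients[1.0] == pytest.approx(2.0, abs=1e-8)
        assert formula.coefficients[4.0] == pytest.approx(3.0, abs=1e-8)
        assert 2.0 not in formula.coefficients
        assert formula.r == pytest.approx(1.0, abs=1e-10)

    def test_pure_noise_column_rarely_selected(self):
        selected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            c1 = rng.uniform(1, 10, 30)
            c4 = rng.uniform(1, 10, 30)
            noise = rng.uniform(1, 10, 30)
            frame = pd.DataFrame({1.0: c1, 4.0: c4, 8.0: noise})
            auc = 5 + 2 * c1 + 3 * c4 + rng.normal(0, 0.5, 30)
            formula = fit_lss_regression(auc, frame, SamplingScheme((1.0, 4.0, 8.0)))
            if 8.0 in formula.coefficients:
                selected += 1
        assert selected <= 10

    def test_too_few_subjects_rejected(self):
        frame = pd.DataFrame({1.0: np.arange(5.0), 2.0: np.arange(5.0), 4.0: np.arange(5.0)})
        with pytest.raises(ValueError):
            fit_lss_regression(np.arange(5.0), frame, SamplingScheme((1.0, 2.0, 4.0)))


def _noise_free_subject(model, stage=1, dose=500.0):
    p = apply_stage_covariates(model, stage)
    doses = tuple(DoseEvent(12.0 * k, dose) for k in range(7))
    t = 72.0 + np.asarray(DESIGN)
    f = conc_profile(p, doses, t)
    return SubjectRecord(
        "nf", stage, doses,
        tuple(Observation(float(a), float(b)) for a, b in zip(t, f)),
        {"STAGE": float(stage)},
    )


class TestBayesian:
    def test_full_scheme_on_typical_subject_reproduces_trapezoid(self, final_model):
        # with proportional error the MAP mode is pulled toward smaller
        # predictions through the log-variance term, so self-consistency is
        # exact only in the small-noise limit; sigma = 0.05 makes that
        # interaction shrinkage negligible
        quiet = dataclasses.replace(final_model, sigma_prop=0.05)
        subject = _noise_free_subject(quiet)
        predicted = bayesian_lss_auc(quiet, subject, SamplingScheme(DESIGN))
        t, dv, _ = subject.observation_arrays()
        observed = trapezoid_auc(t - 72.0, dv)
        assert predicted == pytest.approx(observed, rel=0.01)

    def test_missing_scheme_time_names_the_time(self, final_model):
        subject = _noise_free_subject(final_model)
        with pytest.raises(ValueError, match="5"):
            bayesian_lss_auc(final_model, subject, SamplingScheme((0.0, 1.0, 5.0)))

    def test_scheme_needs_three_points(self):
        with pytest.raises(ValueError):
            SamplingScheme((1.0, 2.0))


class TestEvaluateSchemes:
    def test_four_point_scheme_not_worse_than_nested_three_point(self, final_model,
                                                                 full_cohort):
        ev = evaluate_schemes(final_model, full_cohort,
                              schemes=((1.0, 2.0, 4.0), (0.0, 1.0, 2.0, 4.0)),
                              methods=("bayesian",))
        frame = ev.frame
        for stage in (0, 1):
            r3 = frame[(frame.stage == stage) & (frame.n_times == 3)].r.iloc[0]
            r4 = frame[(frame.stage == stage) & (frame.n_times == 4)].r.iloc[0]
            assert r4 >= r3 - 0.03  # nesting, allowing estimation noise

    def test_regression_leave_one_out_close_to_in_sample(self, final_model,
                                                         full_cohort):
        in_sample = evaluate_schemes(final_model, full_cohort,
                                     schemes=((0.0, 1.0, 2.0, 4.0),),
                                     methods=("regression",))
        loo = evaluate_schemes(final_model, full_cohort,
                               schemes=((0.0, 1.0, 2.0, 4.0),),
                               methods=("regression",), leave_one_out=True)
        for stage in (0, 1):
            a = in_sample.frame[in_sample.frame.stage == stage].r.iloc[0]
            b = loo.frame[loo.frame.stage == stage].r.iloc[0]
            assert abs(a - b) < 0.05

    def test_all_points_regression_is_exact_by_construction(self, final_model,
                                                            full_cohort):
        # the trapezoid AUC is a fixed linear combination of the design
        # concentrations, so the all-points equation reproduces it exactly
        ev = evaluate_schemes(final_model, full_cohort, schemes=(DESIGN,),
                              methods=("regression",))
        assert (ev.frame.r > 0.999).all()
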