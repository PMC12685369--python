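"""Maximum-likelihood fitting, hazard ratios, interaction and strata."""

import numpy as np
import pandas as pd
import pytest

import frailmsm as fm
from frailmsm.fit import (
    AGE_BANDS,
    crude_initial_values,
    fit_interaction_model,
    fit_mle,
    fit_stratified,
    hazard_ratio_table,
)
from frailmsm.model import N_TRANSITIONS, TRANSITIONS, IntensityModel
from frailmsm.panel import PanelDataset


class TestCrudeInitialValues:
    def test_occurrence_over_exposure(self):
        # 10 subject-years in robust with two 1->2 changes -> q12 = 0.2
        rows = []
        for s in range(5):
            rows += [(s, 0.0, 1), (s, 2.0, 2 if s < 2 else 1)]
        data = PanelDataset(pd.DataFrame(rows, columns=["subject_id", "time",
                                                        "state"]))
        model = crude_initial_values(data)
        k = TRANSITIONS.index((1, 2))
        assert model.q0[k] == pytest.approx(2 / 10)

    def test_unobserved_transitions_floored(self):
        rows = [(1, 0.0, 1), (1, 2.0, 1), (2, 0.0, 2), (2, 2.0, 2),
                (3, 0.0, 3), (3, 2.0, 3)]
        data = PanelDataset(pd.DataFrame(rows, columns=["subject_id", "time",
                                                        "state"]))
        model = crude_initial_values(data)
        # no deaths observed: every rate to death sits at the 1e-3 floor
        for pair in ((1, 4), (2, 4), (3, 4)):
            assert model.q0[TRANSITIONS.index(pair)] == pytest.approx(1e-3)

    def test_within_factor_three_of_truth_on_simulated_cohort(self):
        # moderate rates relative to the wave spacing, so observed adjacent
        # changes approximate true jumps and occurrence/exposure is sane
        true = IntensityModel(
            log_q0=np.log([0.15, 0.01, 0.15, 0.12, 0.02, 0.15, 0.10]))
        cfg = fm.SyntheticCohortConfig(n_subjects=2000, seed=7,
                                       true_model=true)
        panel = fm.generate_cohort(cfg)
        crude = crude_initial_values(panel)
        for pair in ((1, 2), (2, 1), (2, 3), (3, 2), (3, 4)):
            k = TRANSITIONS.index(pair)
            ratio = crude.q0[k] / true.q0[k]
            assert 1 / 3 < ratio < 3, (pair, ratio)


class TestFitMLE:
    def test_parameter_recovery_within_15_percent(self, recovery_fit,
                                                  baseline_model):
        panel, fit = recovery_fit
        assert fit.converged
        truth = baseline_model.q0
        counts = panel.observations.groupby("subject_id")["state"]
        for pair in ((1, 2), (2, 1), (2, 3), (3, 2), (3, 4)):
            k = TRANSITIONS.index(pair)
            rel = abs(fit.model.q0[k] / truth[k] - 1)
            assert rel < 0.15, f"{pair}: {rel:.3f}"

    def test_binary_covariate_hr_recovery(self):
        beta = np.zeros((N_TRANSITIONS, 1))
        k = TRANSITIONS.index((2, 3))
        beta[k, 0] = np.log(1.5)
        true = IntensityModel(log_q0=fm.default_baseline_model().log_q0,
                              beta=beta, covariates=("male",))
        cfg = fm.SyntheticCohortConfig(n_subjects=3000, seed=17,
                                       true_model=true,
                                       death_convention="interval")
        panel = fm.generate_cohort(cfg)
        fit = fit_mle(panel, ("male",), age_timevarying=False)
        hr = hazard_ratio_table(fit)
        est = hr.loc[(hr.transition == "pre_frail->frail")
                     & (hr.covariate == "male"), "hr"].iloc[0]
        assert 1.3 < est < 1.75

    def test_refit_from_optimum_is_fixed_point(self, recovery_fit):
        panel, fit = recovery_fit
        refit = fit_mle(panel, initial=fit.model, compute_covariance=False)
        np.testing.assert_allclose(refit.theta, fit.theta, atol=1e-4)
        assert refit.log_likelihood == pytest.approx(fit.log_likelihood,
                                                     abs=1e-6)

    def test_optimum_beats_crude_inits(self, recovery_fit):
        panel, fit = recovery_fit
        crude = crude_initial_values(panel)
        ll0 = fm.panel_log_likelihood(crude, panel)
        assert fit.log_likelihood >= ll0

    def test_nested_model_loglik_ordering(self, small_panel):
        f0 = fit_mle(small_panel, compute_covariance=False)
        f1 = fit_mle(small_panel, ("male",), compute_covariance=False,
                     age_timevarying=False)
        assert f0.log_likelihood <= f1.log_likelihood + 1e-6


class TestHazardRatioTable:
    @staticmethod
    def _fit_with(beta_val, se):
        model = IntensityModel(
            log_q0=fm.default_baseline_model().log_q0,
            beta=np.full((N_TRANSITIONS, 1), beta_val),
            covariates=("male",))
        p = len(model.theta)
        cov = np.zeros((p, p))
        cov[N_TRANSITIONS:, N_TRANSITIONS:] = np.eye(N_TRANSITIONS) * se**2
        return fm.FittedMSM(model=model, log_likelihood=0.0, converged=True,
                            n_iter=1, covariance=cov, n_subjects=1,
                            n_intervals=1)

    def test_null_effect_wald_interval(self):
        hr = hazard_ratio_table(self._fit_with(0.0, 0.1))
        row = hr.iloc[0]
        assert row["hr"] == pytest.approx(1.0)
        assert row["ci_low"] == pytest.approx(np.exp(-1.96 * 0.1), rel=1e-3)
        assert row["ci_high"] == pytest.approx(np.exp(1.96 * 0.1), rel=1e-3)

    def test_wald_arithmetic(self):
        hr = hazard_ratio_table(self._fit_with(np.log(2), 0.05))
        row = hr.iloc[0]
        assert row["hr"] == pytest.approx(2.0)
        assert row["ci_low"] == pytest.approx(2 * np.exp(-1.96 * 0.05),
                                              rel=1e-3)
        assert row["ci_high"] == pytest.approx(2 * np.exp(1.96 * 0.05),
                                               rel=1e-3)

    def test_missing_covariance_flags_rows(self):
        fit = self._fit_with(0.0, 0.1)
        fit.covariance = None
        hr = hazard_ratio_table(fit)
        assert not hr["ci_available"].any()
        assert hr["ci_low"].isna().all()


class TestInteractionModel:
    def test_requires_age_and_male(self, small_panel):
        with pytest.raises(ValueError):
            fit_interaction_model(small_panel, ("age",))

    def test_product_column_zero_for_females(self):
        from frailmsm.panel import design_matrix
        cov = pd.DataFrame({"age": [50.0, 70.0], "male": [0.0, 1.0],
                            "education": [0, 1], "married": [1, 1],
                            "urban": [0, 1], "ever_smoker": [0, 1],
                            "ever_drinker": [0, 1]})
        Z = design_matrix(cov, ("age", "male", "age_x_male"),
                          {"age": 60.0})
        assert Z[0, 2] == 0.0                     # female row
        assert Z[1, 2] == pytest.approx(10.0)     # (70-60) * 1

    def test_interaction_fit_runs_and_reports_term(self):
        cfg = fm.SyntheticCohortConfig(n_subjects=400, seed=19,
                                       death_convention="interval")
        panel = fm.generate_cohort(cfg)
        fit = fit_interaction_model(panel, ("age", "male"),
                                    compute_covariance=False)
        hr = hazard_ratio_table(fit)
        assert (hr.covariate == "age_x_male").sum() == N_TRANSITIONS


class TestStratified:
    def test_band_edges_closed_on_left(self):
        assert AGE_BANDS[0] == (45.0, 55.0)
        cfg = fm.SyntheticCohortConfig(n_subjects=500, seed=23)
        panel = fm.generate_cohort(cfg)
        cov = panel.covariates
        bands = [(cov["age"] >= lo) & (cov["age"] < hi)
                 for lo, hi in AGE_BANDS]
        # each subject aged >= 45 falls in exactly one band; 54.9 -> 45-54
        total = sum(b.astype(int) for b in bands)
        assert (total == 1).all()

    def test_gender_strata_recover_common_dynamics(self, baseline_model):
        cfg = fm.SyntheticCohortConfig(n_subjects=3000, seed=29,
                                       true_model=baseline_model)
        panel = fm.generate_cohort(cfg)
        fits = fit_stratified(panel, age_bands=None, by_gender=True,
                              compute_covariance=False)
        assert set(fits) == {"female", "male"}
        for f in fits.values():
            ratios = f.model.q0 / baseline_model.q0
            for pair in ((1, 2), (2, 1), (2, 3), (3, 2)):
                assert abs(ratios[TRANSITIONS.index(pair)] - 1) < 0.3

    def test_underpopulated_stratum_skipped(self):
        cfg = fm.SyntheticCohortConfig(n_subjects=120, seed=31)
        panel = fm.generate_cohort(cfg)
        with pytest.warns(fm.fit.FitWarning if hasattr(fm, "fit") else UserWarning):
            fits = fit_stratified(panel, age_bands=AGE_BANDS,
                                  min_subjects=100,
                                  compute_covariance=False)
        assert len(fits) < len(AGE_BANDS)
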