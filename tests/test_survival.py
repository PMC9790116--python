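"""Kaplan-Meier and Cox model tests against hand calculations, a grid-search
oracle and lifelines as an independent implementation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointvitals.base import ConvergenceError
from jointvitals.survival import (
    CoxPH,
    KaplanMeier,
    breslow_cumhaz,
    cox_partial_loglik,
    hazard_ratio_table,
    wald_table,
)


def _surv(times, events, **cov):
    return pd.DataFrame(
        {"observed_time_h": times, "event": events, **cov}
    )


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        km = KaplanMeier().fit(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(km.survival_, [2 / 3, 1 / 3, 0.0])

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 2, censoring at 2.5: S(2) = (2/3) * (1/2)
        km = KaplanMeier().fit(_surv([1.0, 2.5, 2.0], [1, 0, 1]))
        assert km.survival_[-1] == pytest.approx(1 / 3)
        # censoring before the second event removes the subject from the
        # risk set, so the last factor becomes (1 - 1/1)
        km2 = KaplanMeier().fit(_surv([1.0, 1.5, 2.0], [1, 0, 1]))
        assert km2.survival_[-1] == pytest.approx(0.0)

    def test_median_is_first_time_below_half(self):
        km = KaplanMeier().fit(_surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1]))
        assert km.median_ == 2.0

    def test_median_missing_when_never_reached(self):
        km = KaplanMeier().fit(_surv([1.0, 2.0, 3.0], [1, 0, 0]))
        assert np.isnan(km.median_)

    def test_matches_lifelines_on_simulated_cohort(self, study_cohort):
        from lifelines import KaplanMeierFitter

        surv = study_cohort.dataset.survival
        km = KaplanMeier().fit(surv)
        ll = KaplanMeierFitter().fit(surv["observed_time_h"], surv["event"])
        assert km.median_ == pytest.approx(ll.median_survival_time_)
        grid = [24.0, 48.0, 72.0, 90.0]
        assert np.allclose(km.survival_at(grid), ll.predict(grid).to_numpy())

    def test_all_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            KaplanMeier().fit(_surv([0.0, -1.0], [1, 1]))

    def test_survival_monotone_within_unit_interval(self, study_cohort):
        km = KaplanMeier().fit(study_cohort.dataset.survival)
        assert km.survival_[0] <= 1.0
        assert (np.diff(km.survival_) <= 1e-12).all()
        assert (km.survival_ >= 0).all()


class TestPartialLikelihood:
    def test_null_value_is_minus_sum_log_risk_sets(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        X = np.zeros((4, 1))
        expected = -(np.log(4) + np.log(3) + np.log(2) + np.log(1))
        assert cox_partial_loglik(np.zeros(1), surv, X) == pytest.approx(expected)

    def test_grid_search_oracle_matches_newton(self):
        surv = _surv([2.0, 3.0, 5.0, 7.0], [1, 1, 0, 1], x=[1.0, 0.0, 1.0, 0.0])
        X = surv[["x"]].to_numpy()
        grid = np.arange(-3.0, 3.0001, 0.01)
        vals = [cox_partial_loglik(np.array([b]), surv, X) for b in grid]
        b_grid = grid[int(np.argmax(vals))]
        fit = CoxPH().fit(surv, ["x"])
        assert abs(fit.beta_["x"] - b_grid) <= 0.01

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(-50, 50))
    def test_invariant_to_covariate_shift(self, seed, shift):
        rng = np.random.default_rng(seed)
        n = 12
        surv = _surv(
            rng.uniform(1, 10, n), rng.integers(0, 2, n), x=rng.standard_normal(n)
        )
        if surv["event"].sum() == 0:
            surv.loc[0, "event"] = 1
        X = surv[["x"]].to_numpy()
        beta = np.array([0.7])
        a = cox_partial_loglik(beta, surv, X)
        b = cox_partial_loglik(beta, surv, X + shift)
        assert a == pytest.approx(b, abs=1e-8)


class TestCoxFit:
    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(5)
        n = 150
        x1 = rng.standard_normal(n)
        x2 = (rng.random(n) < 0.4).astype(float)
        T = rng.exponential(1.0 / np.exp(0.5 * x1 - 1.0 * x2))
        C = rng.exponential(2.0, n)
        surv = _surv(np.minimum(T, C), (T <= C).astype(int), x1=x1, x2=x2)
        fit = CoxPH().fit(surv, ["x1", "x2"])
        ref = CoxPHFitter().fit(
            surv.rename(columns={"observed_time_h": "T", "event": "E"}), "T", "E"
        )
        assert np.allclose(fit.beta_.to_numpy(), ref.params_.to_numpy(), atol=1e-4)
        assert np.allclose(fit.se_.to_numpy(), ref.standard_errors_.to_numpy(), atol=1e-4)
        assert fit.loglik_ == pytest.approx(ref.log_likelihood_, abs=1e-6)

    def test_group_label_symmetry_gives_zero_coefficient(self):
        surv = _surv(
            [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            [1, 1, 1, 1, 1, 1],
            g=[0.0, 0.0, 0.0, 1.0, 1.0, 1.0],
        )
        fit = CoxPH().fit(surv, ["g"])
        assert abs(fit.beta_["g"]) < 1e-8

    def test_binary_covariate_recovery_across_seeds(self, null_params):
        # gamma = 0 cohorts; a single binary covariate with a known log-HR
        # echoing the published severe-pneumonia effect
        from dataclasses import replace

        from jointvitals.hazard import invert_cumulative_hazard

        true = -1.581
        est, ses = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n = 120
            x = (rng.random(n) < 0.4).astype(float)
            lam = 0.02
            eta = true * x
            T = invert_cumulative_hazard(
                np.array([0.0, 1e9]), np.array([lam]), eta, np.zeros(n),
                -np.log(rng.uniform(size=n)),
            )
            C = np.full(n, 120.0)
            surv = _surv(np.minimum(T, C), (T <= C).astype(int), x=x)
            fit = CoxPH().fit(surv, ["x"])
            est.append(fit.beta_["x"])
            ses.append(fit.se_["x"])
        mc_se = np.std(est) / np.sqrt(len(est))
        assert abs(np.mean(est) - true) < 3 * mc_se

    def test_hr_equals_exp_beta_exactly(self, study_cohort):
        surv = study_cohort.dataset.survival
        design = study_cohort.dataset.covariate_design()
        frame = pd.concat(
            [surv[["observed_time_h", "event"]], design[["severity[severe]"]]], axis=1
        )
        fit = CoxPH().fit(frame, ["severity[severe]"])
        assert np.array_equal(
            fit.hazard_ratios_.to_numpy(), np.exp(fit.beta_.to_numpy())
        )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            CoxPH().fit(_surv([1.0, 2.0], [0, 0], x=[0.0, 1.0]), ["x"])

    def test_collinear_columns_named(self):
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1],
                     a=[1.0, 2.0, 3.0, 4.0], b=[2.0, 4.0, 6.0, 8.0])
        with pytest.raises(ValueError, match="rank deficient"):
            CoxPH().fit(surv, ["a", "b"])

    def test_perfect_separation_flagged(self):
        # covariate orders the failures perfectly: monotone likelihood
        surv = _surv([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1] * 6,
                     x=[5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        with pytest.raises(ConvergenceError):
            CoxPH().fit(surv, ["x"])


class TestBreslow:
    def test_null_model_equals_nelson_aalen(self):
        fit = CoxPH().fit(_surv([1.0, 2.0, 3.0], [1, 1, 1]), X=np.zeros((3, 0)))
        bh = breslow_cumhaz(fit)
        assert np.allclose(bh["increment"], [1 / 3, 1 / 2, 1.0])

    def test_hand_computed_breslow_with_covariate(self):
        # 4 subjects, events at 1 and 3; verify the risk-set sums by hand
        surv = _surv([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0], x=[1.0, 0.0, 0.0, 1.0])
        fit = CoxPH().fit(surv, ["x"])
        b = fit.beta_["x"]
        w = np.exp(b * surv["x"].to_numpy())
        expected = [1.0 / w.sum(), 1.0 / (w[2] + w[3])]
        bh = breslow_cumhaz(fit)
        assert np.allclose(bh["increment"], expected)

    def test_nondecreasing_on_simulated_cohort(self, study_cohort):
        surv = study_cohort.dataset.survival
        design = study_cohort.dataset.covariate_design()
        frame = pd.concat(
            [surv[["observed_time_h", "event"]], design[["severity[severe]"]]], axis=1
        )
        fit = CoxPH().fit(frame, ["severity[severe]"])
        assert (np.diff(breslow_cumhaz(fit)["cumhaz"]) >= 0).all()


class TestWaldTable:
    def test_zero_coefficient_gives_unit_hr_and_p_one(self):
        tab = wald_table(["x"], [0.0], [0.5])
        assert tab.loc["x", "hr"] == 1.0
        assert tab.loc["x", "p"] == 1.0

    def test_ci_is_exp_of_beta_pm_1p96_se(self):
        tab = wald_table(["x"], [0.4], [0.1])
        z = 1.959963984540054
        assert tab.loc["x", "hr_lower"] == pytest.approx(np.exp(0.4 - z * 0.1))
        assert tab.loc["x", "hr_upper"] == pytest.approx(np.exp(0.4 + z * 0.1))

    def test_table_from_fit(self, study_cohort):
        surv = study_cohort.dataset.survival
        design = study_cohort.dataset.covariate_design()
        frame = pd.concat(
            [surv[["observed_time_h", "event"]], design[["severity[severe]"]]], axis=1
        )
        fit = CoxPH().fit(frame, ["severity[severe]"])
        tab = hazard_ratio_table(fit)
        assert list(tab.index) == ["severity[severe]"]
        assert tab["hr"].iloc[0] == pytest.approx(np.exp(tab["beta"].iloc[0]))
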