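"""Joint model: hazard primitives, closed-form cumulative hazard against
numerical quadrature, separability at gamma = 0, integrator agreement and
the initializer contract."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from jointvitals.design import prepare
from jointvitals.joint import (
    IntegratorConfig,
    JointModel,
    cumulative_hazard,
    current_value,
    default_knots,
    initialize_from_separate,
    log_hazard,
    marginal_loglik_joint,
    subject_loglik_given_b,
)
from jointvitals.mlmm import MultivariateLMM, marginal_loglik_mlmm
from jointvitals.simulate import SimulationConfig, simulate_cohort
from jointvitals.survival import wald_table
from tests.conftest import FORMULAS, SURV_COV


@pytest.fixture(scope="module")
def cohort5(true_params):
    sim = simulate_cohort(SimulationConfig(n=5, seed=11), true_params)
    prepared = prepare(sim.dataset, FORMULAS, SURV_COV)
    design = sim.dataset.covariate_design()
    return sim, prepared, design


class TestCurrentValue:
    def test_reference_subject_at_admission_is_intercept(self, true_params):
        row = pd.Series(
            {"severity[mild-severe]": 0.0, "severity[severe]": 0.0}
        )
        m = current_value(np.zeros(6), row, true_params, "RR", 0.0)
        assert m == pytest.approx(true_params.mlmm.beta["RR"]["Intercept"])

    def test_linear_in_time_with_visit_slope(self, true_params):
        row = pd.Series({"severity[mild-severe]": 0.0, "severity[severe]": 1.0})
        b = np.array([1.0, 0.5, 0, 0, 0, 0])
        m6 = current_value(b, row, true_params, "RR", 6.0)
        m0 = current_value(b, row, true_params, "RR", 0.0)
        expected_slope = true_params.mlmm.beta["RR"]["visit"] + 0.5
        assert m6 - m0 == pytest.approx(expected_slope)

    def test_matches_mlmm_trajectory_prediction(self, true_params, cohort5):
        sim, prepared, design = cohort5
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False)
        fit.prepared_ = prepared
        fit.params_ = true_params.mlmm
        fit.beta_vec_ = prepared.pack_beta(true_params.mlmm.beta)
        sid = sim.dataset.subject_ids[2]
        means, _ = fit.blup()
        b = means.loc[sid].to_numpy()
        times = np.array([0.0, 12.0, 30.0])
        pred = fit.predict_trajectory(sid, "PR", times)
        idx = sim.dataset.subject_ids.index(sid)
        mine = [
            current_value(b, design.iloc[idx], true_params, "PR", t) for t in times
        ]
        assert np.allclose(pred, mine, atol=1e-10)


class TestHazard:
    def test_null_association_log_hazard_is_baseline_plus_zeta(self, true_params):
        p0 = replace(true_params.copy(), gamma=np.zeros(3))
        row = pd.Series({"severity[mild-severe]": 0.0, "severity[severe]": 0.0})
        lh = log_hazard(np.zeros(6), row, p0, 30.0)
        assert lh == pytest.approx(p0.log_lambda[0])

    def test_zero_before_first_knot(self, true_params):
        row = pd.Series({"severity[mild-severe]": 0.0, "severity[severe]": 0.0})
        assert log_hazard(np.zeros(6), row, true_params, 5.0) == -np.inf

    def test_association_shift_is_gamma_times_current_value(self, true_params, cohort5):
        sim, _, design = cohort5
        b = sim.random_effects.iloc[0].to_numpy()
        row = design.iloc[0]
        delta = 0.05
        p2 = replace(true_params.copy(), gamma=true_params.gamma + np.array([delta, 0, 0]))
        t = 40.0
        shift = log_hazard(b, row, p2, t) - log_hazard(b, row, true_params, t)
        assert shift == pytest.approx(delta * current_value(b, row, true_params, "RR", t))

    def test_cumulative_hazard_matches_quadrature(self, true_params, cohort5):
        sim, _, design = cohort5
        for i in (0, 2):
            b = sim.random_effects.iloc[i].to_numpy()
            row = design.iloc[i]
            for t in (30.0, 75.0, 96.0):
                closed = cumulative_hazard(b, row, true_params, t)
                num, _ = quad(
                    lambda s: np.exp(log_hazard(b, row, true_params, s))
                    if s > true_params.knots[0]
                    else 0.0,
                    0.0,
                    t,
                    points=list(true_params.knots[:-1]),
                    limit=400,
                )
                assert abs(closed - num) <= 1e-10 * max(1.0, abs(num))

    def test_drift_continuity_at_zero(self, true_params, cohort5):
        # C -> 0 limit: shrink gamma so the per-hour drift is ~1e-13
        sim, _, design = cohort5
        row = design.iloc[0]
        b = np.zeros(6)
        base = true_params
        tiny = replace(base.copy(), gamma=base.gamma * 1e-13)
        zero = replace(base.copy(), gamma=np.zeros(3))
        # rescale the tiny-gamma baseline so the constant parts match
        l_tiny = cumulative_hazard(b, row, tiny, 90.0)
        l_zero = cumulative_hazard(b, row, zero, 90.0)
        assert l_tiny == pytest.approx(l_zero, rel=1e-9)

    def test_nondecreasing_in_time(self, true_params, cohort5):
        sim, _, design = cohort5
        b = sim.random_effects.iloc[1].to_numpy()
        ts = np.linspace(0.0, 120.0, 60)
        vals = [cumulative_hazard(b, design.iloc[1], true_params, t) for t in ts]
        assert (np.diff(vals) >= -1e-12).all()


class TestSubjectLoglik:
    def test_censored_subject_without_measurements_is_minus_cumhaz(
        self, true_params, cohort5
    ):
        from dataclasses import replace as dc_replace

        sim, prepared, design = cohort5
        sub = prepared.subjects[0]
        empty = dc_replace(
            sub,
            y=np.empty(0),
            k_row=np.empty(0, int),
            visit=np.empty(0),
            X=np.empty((0, prepared.p_beta)),
            Z=np.empty((0, 6)),
            delta=0,
        )
        b = sim.random_effects.iloc[0].to_numpy()
        ll = subject_loglik_given_b(b, empty, true_params)
        lam = cumulative_hazard(b, design.iloc[0], true_params, sub.T)
        assert ll == pytest.approx(-lam, rel=1e-10)

    def test_hand_computation_two_measurements(self, true_params, cohort5):
        from dataclasses import replace as dc_replace

        sim, prepared, design = cohort5
        sub = prepared.subjects[1]
        b = sim.random_effects.iloc[1].to_numpy()
        ll = subject_loglik_given_b(b, sub, true_params)
        # hand: sum of normal densities at the current values + survival part
        expected = 0.0
        for j in range(len(sub.y)):
            k = sub.k_row[j]
            name = ("RR", "PR", "OX")[k]
            m = current_value(b, design.iloc[1], true_params, name, sub.visit[j] * 6.0)
            expected += norm.logpdf(sub.y[j], m, true_params.mlmm.sigma[k])
        expected -= cumulative_hazard(b, design.iloc[1], true_params, sub.T)
        if sub.delta:
            expected += log_hazard(b, design.iloc[1], true_params, sub.T)
        assert ll == pytest.approx(expected, rel=1e-10)


class TestMarginal:
    def test_separability_at_null_association(self, null_cohort):
        sim, p0 = null_cohort
        prepared = prepare(sim.dataset, FORMULAS, SURV_COV)
        design = sim.dataset.covariate_design()
        joint_ll = marginal_loglik_joint(p0, prepared)
        mlmm_ll = marginal_loglik_mlmm(p0.mlmm, sim.dataset)
        ph = 0.0
        for i, sub in enumerate(prepared.subjects):
            bz = np.zeros(6)
            ph -= cumulative_hazard(bz, design.iloc[i], p0, sub.T)
            if sub.delta:
                ph += log_hazard(bz, design.iloc[i], p0, sub.T)
        assert joint_ll == pytest.approx(mlmm_ll + ph, abs=1e-8)

    def test_gh_and_monte_carlo_agree(self, true_params, cohort5):
        sim, prepared, _ = cohort5
        gh = marginal_loglik_joint(true_params, prepared)
        mc = marginal_loglik_joint(
            true_params,
            prepared,
            IntegratorConfig(method="monte-carlo", mc_draws=10000, seed=4),
        )
        assert abs(gh - mc) / abs(gh) < 1e-3

    def test_vanishing_D_collapses_to_plug_in_loglik(self, true_params, cohort5):
        sim, prepared, _ = cohort5
        gaps = []
        for scale in (1e-6, 1e-8, 1e-10):
            p = true_params.copy()
            p.mlmm.D = np.eye(6) * scale
            ll = marginal_loglik_joint(p, prepared)
            plug = sum(
                subject_loglik_given_b(np.zeros(6), sub, p)
                for sub in prepared.subjects
            )
            gaps.append(abs(ll - plug))
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 0.1

    def test_integrator_config_validation(self):
        with pytest.raises(ValueError):
            IntegratorConfig(method="simpson")
        with pytest.raises(ValueError):
            IntegratorConfig(mc_draws=3)


class TestInitializer:
    def test_gamma_starts_at_zero_and_loglik_matches_separability(self, null_cohort):
        sim, p0 = null_cohort
        ds = sim.dataset
        mlmm = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(ds)
        knots = default_knots(ds.survival, 4)
        init = initialize_from_separate(mlmm, None, knots, surv=ds.survival)
        assert np.array_equal(init.gamma, np.zeros(3))
        prepared = prepare(ds, FORMULAS, [])
        ll = marginal_loglik_joint(init, prepared)
        assert np.isfinite(ll)
        design = ds.covariate_design()
        ph = 0.0
        for i, sub in enumerate(prepared.subjects):
            bz = np.zeros(6)
            ph -= cumulative_hazard(bz, design.iloc[i], init, sub.T)
            if sub.delta:
                ph += log_hazard(bz, design.iloc[i], init, sub.T)
        assert ll == pytest.approx(mlmm.loglik_ + ph, abs=1e-6)

    def test_initializer_finite_over_seeds(self, true_params):
        for seed in range(6):
            sim = simulate_cohort(SimulationConfig(n=30, seed=100 + seed), true_params)
            ds = sim.dataset
            mlmm = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(ds)
            knots = default_knots(ds.survival, 4)
            init = initialize_from_separate(mlmm, None, knots, surv=ds.survival)
            prepared = prepare(ds, FORMULAS, [])
            assert np.isfinite(marginal_loglik_joint(init, prepared))

    def test_default_knots_span_event_range(self, study_cohort):
        surv = study_cohort.dataset.survival
        knots = default_knots(surv, 5)
        et = surv.loc[surv["event"] == 1, "observed_time_h"]
        assert knots[0] == pytest.approx(et.min())
        assert knots[-1] >= et.max()
        assert (np.diff(knots) > 0).all()


class TestAssociationTable:
    def test_hazard_ratios_match_printed_association_values(self):
        tab = wald_table(
            ["RR", "PR", "OX"], [-0.297, -0.121, 0.5452], [0.041, 0.034, 0.2007]
        )
        assert tab["hr"].round(3).tolist() == [0.743, 0.886, 1.725]

    def test_zero_association_gives_unit_hazard_ratio(self):
        tab = wald_table(["RR"], [0.0], [0.1])
        assert tab["hr"].iloc[0] == 1.0
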