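"""Multivariate linear mixed model: exact marginal likelihood, fitting,
BLUPs and diagnostics, with statsmodels MixedLM as the independent oracle."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from jointvitals.data import CohortDataset
from jointvitals.design import formulas_from_params, prepare
from jointvitals.mlmm import (
    MultivariateLMM,
    marginal_loglik_mlmm,
    qq_points,
)
from jointvitals.params import K, MLMMParams
from jointvitals.simulate import SimulationConfig, simulate_cohort
from tests.conftest import FORMULAS


def _single_obs_dataset(value=52.0):
    long = pd.DataFrame(
        {"subject_id": ["a"], "outcome": ["RR"], "time_h": [0.0], "value": [value]}
    )
    surv = pd.DataFrame(
        {"subject_id": ["a"], "observed_time_h": [96.0], "event": [0]}
    )
    return CohortDataset(long, surv)


def _params_intercept_only(d11=4.0, sigma=2.0, mu=50.0):
    D = np.eye(2 * K) * 1e-4
    D[0, 0] = d11
    beta = {"RR": pd.Series({"Intercept": mu, "visit": 0.0})}
    return MLMMParams(beta, D, np.array([sigma, 1.0, 1.0]))


class TestMarginalLoglik:
    def test_single_observation_equals_scalar_normal(self):
        ds = _single_obs_dataset(52.0)
        p = _params_intercept_only(d11=4.0, sigma=2.0, mu=50.0)
        ll = marginal_loglik_mlmm(p, ds)
        expected = norm.logpdf(52.0, loc=50.0, scale=np.sqrt(4.0 + 4.0))
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_block_diagonal_D_factorizes_over_outcomes(self, true_params):
        # cross-outcome blocks zeroed: MLMM loglik = sum of per-outcome LMMs
        sim = simulate_cohort(SimulationConfig(n=12, seed=21), true_params)
        ds = sim.dataset
        D = true_params.mlmm.D.copy()
        Dbd = np.zeros_like(D)
        for k in range(K):
            Dbd[2 * k : 2 * k + 2, 2 * k : 2 * k + 2] = D[
                2 * k : 2 * k + 2, 2 * k : 2 * k + 2
            ]
        p = MLMMParams(
            {k: v.copy() for k, v in true_params.mlmm.beta.items()},
            Dbd,
            true_params.mlmm.sigma.copy(),
        )
        total = marginal_loglik_mlmm(p, ds)
        parts = 0.0
        for k_name in ("RR", "PR", "OX"):
            sub_long = ds.longitudinal[ds.longitudinal["outcome"] == k_name]
            sub_ds = CohortDataset(sub_long, ds.survival, ds.covariate_spec)
            pk = MLMMParams({k_name: p.beta[k_name].copy()}, Dbd, p.sigma.copy())
            parts += marginal_loglik_mlmm(pk, sub_ds)
        assert total == pytest.approx(parts, abs=1e-8)

    def test_agrees_with_dense_multivariate_normal_oracle(self, true_params):
        sim = simulate_cohort(SimulationConfig(n=5, seed=8), true_params)
        ds = sim.dataset
        p = true_params.mlmm
        prepared = prepare(ds, formulas_from_params(p))
        beta_vec = prepared.pack_beta(p.beta)
        expected = 0.0
        for sub in prepared.subjects:
            mean = sub.X @ beta_vec
            V = sub.Z @ p.D @ sub.Z.T + np.diag(p.sigma[sub.k_row] ** 2)
            expected += multivariate_normal.logpdf(sub.y, mean, V)
        assert marginal_loglik_mlmm(p, ds) == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_matches_statsmodels_single_outcome(self, true_params):
        import statsmodels.api as sm

        sim = simulate_cohort(SimulationConfig(n=60, seed=17), true_params)
        long = sim.dataset.longitudinal
        rr = long[long["outcome"] == "RR"].copy()
        ds = CohortDataset(rr, sim.dataset.survival, sim.dataset.covariate_spec)
        fit = MultivariateLMM(formulas={"RR": []}, compute_se=False).fit(ds)

        rr["visit"] = rr["time_h"] / 6.0
        exog = sm.add_constant(rr[["visit"]])
        md = sm.MixedLM(
            rr["value"], exog, groups=rr["subject_id"], exog_re=exog
        )
        ref = md.fit(reml=False)
        assert fit.loglik_ == pytest.approx(ref.llf, abs=1e-2)
        assert fit.params_.beta["RR"]["Intercept"] == pytest.approx(
            ref.params["const"], abs=1e-2
        )
        assert fit.params_.beta["RR"]["visit"] == pytest.approx(
            ref.params["visit"], abs=1e-2
        )

    def test_loglik_at_fit_dominates_truth(self, null_cohort):
        sim, p0 = null_cohort
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(sim.dataset)
        assert fit.loglik_ >= marginal_loglik_mlmm(p0.mlmm, sim.dataset) - 1e-6
        assert fit.loglik_ == pytest.approx(
            marginal_loglik_mlmm(fit.params_, sim.dataset), abs=1e-6
        )

    def test_fitted_covariance_is_psd_by_construction(self, null_cohort):
        sim, _ = null_cohort
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(sim.dataset)
        assert np.all(np.linalg.eigvalsh(fit.params_.D) >= -1e-10)
        assert np.all(fit.params_.sigma > 0)

    def test_profiled_beta_is_gls_at_fixed_variance(self, null_cohort):
        # with the variance parameters held fixed the fixed effects solve
        # the generalized-least-squares normal equations exactly
        from jointvitals.mlmm import _profiled

        sim, p0 = null_cohort
        prepared = prepare(sim.dataset, FORMULAS)
        ll, beta, A = _profiled(prepared, p0.mlmm.D, p0.mlmm.sigma)
        c = np.zeros(prepared.p_beta)
        from scipy.linalg import cho_factor, cho_solve

        A2 = np.zeros((prepared.p_beta, prepared.p_beta))
        for sub in prepared.subjects:
            V = sub.Z @ p0.mlmm.D @ sub.Z.T + np.diag(
                p0.mlmm.sigma[sub.k_row] ** 2
            )
            cf = cho_factor(V)
            A2 += sub.X.T @ cho_solve(cf, sub.X)
            c += sub.X.T @ cho_solve(cf, sub.y)
        beta_gls = np.linalg.solve(A2, c)
        assert np.allclose(beta, beta_gls, atol=1e-8)


class TestBlup:
    def test_no_data_subject_gets_prior(self, true_params):
        from dataclasses import replace as dc_replace

        sim = simulate_cohort(SimulationConfig(n=8, seed=4), true_params)
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(sim.dataset)
        # degrade one prepared subject to the no-data case: the posterior
        # must fall back to the prior (mean 0, covariance D)
        sub = fit.prepared_.subjects[0]
        fit.prepared_.subjects[0] = dc_replace(
            sub,
            y=np.empty(0),
            k_row=np.empty(0, int),
            visit=np.empty(0),
            X=np.empty((0, fit.prepared_.p_beta)),
            Z=np.empty((0, 2 * K)),
        )
        means, covs = fit.blup()
        assert np.allclose(means.iloc[0].to_numpy(), 0.0)
        assert np.allclose(covs[0], fit.params_.D)

    def test_single_observation_matches_scalar_ridge_formula(self):
        ds = _single_obs_dataset(53.0)
        p = _params_intercept_only(d11=9.0, sigma=3.0, mu=50.0)
        prepared = prepare(ds, formulas_from_params(p))
        fit = MultivariateLMM(formulas={"RR": []}, compute_se=False)
        # bypass optimization: evaluate the BLUP formula at fixed parameters
        fit.prepared_ = prepared
        fit.params_ = p
        fit.beta_vec_ = prepared.pack_beta(p.beta)
        means, covs = fit.blup()
        # scalar: bhat = d (y - mu) / (d + sigma^2)
        expected = 9.0 * (53.0 - 50.0) / (9.0 + 9.0)
        assert means.iloc[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_average_blup_near_zero_at_large_n(self, true_params):
        sim = simulate_cohort(SimulationConfig(n=400, seed=19), true_params)
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(sim.dataset)
        means, _ = fit.blup()
        prior_sd = np.sqrt(np.diag(fit.params_.D))
        avg = means.mean(axis=0).to_numpy()
        assert np.all(np.abs(avg) < 4 * prior_sd / np.sqrt(len(means)) + 0.05 * prior_sd)


class TestPrediction:
    def test_population_prediction_at_visit_zero_is_intercept_plus_covariates(
        self, null_cohort
    ):
        sim, _ = null_cohort
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(sim.dataset)
        with pytest.warns(UserWarning, match="unknown"):
            pred = fit.predict_trajectory("nobody", "RR", [0.0])
        assert pred[0] == pytest.approx(fit.params_.beta["RR"]["Intercept"])

    def test_subject_prediction_matches_manual_arithmetic(self, null_cohort):
        sim, _ = null_cohort
        fit = MultivariateLMM(formulas=FORMULAS, compute_se=False).fit(sim.dataset)
        sid = sim.dataset.subject_ids[0]
        means, _ = fit.blup()
        b = means.loc[sid].to_numpy()
        sub = next(s for s in fit.prepared_.subjects if s.subject_id == sid)
        beta = fit.params_.beta["RR"]
        t = 12.0
        manual = (
            float(sub.x0["RR"] @ beta.to_numpy())
            + beta["visit"] * 2.0
            + b[0]
            + b[1] * 2.0
        )
        assert fit.predict_trajectory(sid, "RR", [t])[0] == pytest.approx(manual)


class TestQQ:
    def test_standard_normal_quantiles_lie_on_identity(self):
        probs = (np.arange(1, 51) - 0.5) / 50
        residuals = norm.ppf(probs)
        th, sm = qq_points(residuals)
        assert np.allclose(th, sm, atol=1e-12)

    def test_two_points_use_quarter_positions(self):
        th, sm = qq_points([-1.0, 1.0])
        assert np.allclose(th, norm.ppf([0.25, 0.75]))
        assert np.allclose(sm, [-1.0, 1.0])

    def test_large_normal_sample_close_to_identity(self):
        rng = np.random.default_rng(2)
        r = rng.standard_normal(1000)
        th, sm = qq_points((r - r.mean()) / r.std())
        inner = slice(25, 975)  # tails are noisy by nature
        assert np.max(np.abs(th[inner] - sm[inner])) < 0.25

    def test_fewer_than_two_residuals_rejected(self):
        with pytest.raises(ValueError):
            qq_points([0.5])
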