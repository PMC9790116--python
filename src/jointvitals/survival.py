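"""Kaplan-Meier estimation and the Cox proportional-hazards model.

The event here is recovery (discharge from care), so the hazard is the
recovery hazard: a hazard ratio above 1 means *shorter* time to recovery.
Ties are handled with the Breslow approximation throughout; the partial
log-likelihood is exposed publicly so that independent oracles (grid search,
other implementations) can be checked against the same surface the fitter
maximizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .base import BaseEstimator, ConvergenceError, check_is_fitted


def _surv_arrays(surv: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    t = surv["observed_time_h"].to_numpy(dtype=float)
    d = surv["event"].to_numpy(dtype=int)
    return t, d


# ----------------------------------------------------------------------
# Kaplan-Meier
# ----------------------------------------------------------------------

class KaplanMeier(BaseEstimator):
    """Product-limit estimator with Greenwood variance.

    Fitted attributes: ``times_`` (distinct event times), ``survival_``
    (right-continuous step values), ``at_risk_``, ``events_``, ``variance_``
    (Greenwood), ``median_`` (smallest t with S(t) <= 0.5, NaN if never
    reached).
    """

    def fit(self, surv: pd.DataFrame) -> "KaplanMeier":
        t, d = _surv_arrays(surv)
        if len(t) == 0:
            raise ValueError("need at least one subject")
        if np.all(t <= 0):
            raise ValueError("all observed times are non-positive")
        order = np.argsort(t, kind="stable")
        t, d = t[order], d[order]
        event_times = np.unique(t[d == 1])
        n = len(t)
        at_risk, events, surv_prob, var_terms = [], [], [], []
        s = 1.0
        gw = 0.0
        for et in event_times:
            r = int(np.sum(t >= et))
            m = int(np.sum((t == et) & (d == 1)))
            s *= 1.0 - m / r
            if r > m:
                gw += m / (r * (r - m))
            at_risk.append(r)
            events.append(m)
            surv_prob.append(s)
            var_terms.append(s**2 * gw)
        self.times_ = event_times
        self.survival_ = np.array(surv_prob)
        self.at_risk_ = np.array(at_risk, dtype=int)
        self.events_ = np.array(events, dtype=int)
        self.variance_ = np.array(var_terms)
        below = self.survival_ <= 0.5 + 1e-12
        self.median_ = float(self.times_[below][0]) if below.any() else float("nan")
        self.n_ = n
        return self

    def survival_at(self, times) -> np.ndarray:
        """S(t) evaluated at arbitrary times (right-continuous)."""
        check_is_fitted(self, "survival_")
        idx = np.searchsorted(self.times_, np.atleast_1d(times), side="right")
        s = np.concatenate([[1.0], self.survival_])
        return s[idx]


def kaplan_meier(surv: pd.DataFrame) -> KaplanMeier:
    return KaplanMeier().fit(surv)


# ----------------------------------------------------------------------
# Cox partial likelihood (Breslow ties)
# ----------------------------------------------------------------------

def cox_partial_loglik(
    beta: np.ndarray, surv: pd.DataFrame, X: np.ndarray, ties: str = "breslow"
) -> float:
    """Breslow partial log-likelihood at beta.

    ``X`` must be row-aligned with ``surv``.  Exposed as the public oracle
    surface: the fitter maximizes exactly this function.
    """
    ll, _, _ = _pll_grad_hess(np.asarray(beta, dtype=float), surv, np.asarray(X, float), ties)
    return ll


def _pll_grad_hess(beta, surv, X, ties="breslow", want_derivs=False):
    if ties != "breslow":
        raise ValueError("only the Breslow tie approximation is implemented")
    t, d = _surv_arrays(surv)
    n, p = X.shape
    eta = X @ beta
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    order = np.argsort(-t, kind="stable")  # decreasing time
    t_o, d_o, X_o, eta_o = t[order], d[order], X[order], eta[order]
    w = np.exp(eta_o)
    # cumulative risk-set sums walking down in time
    S0 = np.cumsum(w)
    S1 = np.cumsum(X_o * w[:, None], axis=0)
    if want_derivs:
        xx = np.einsum("ij,ik->ijk", X_o, X_o) * w[:, None, None]
        S2 = np.cumsum(xx, axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        # rows i..j-1 share this time; risk set = rows 0..j-1
        ev = np.arange(i, j)[d_o[i:j] == 1]
        m = len(ev)
        if m:
            s0 = S0[j - 1]
            ll += float(np.sum(eta_o[ev])) - m * np.log(s0)
            if want_derivs:
                mu = S1[j - 1] / s0
                grad += X_o[ev].sum(axis=0) - m * mu
                hess -= m * (S2[j - 1] / s0 - np.outer(mu, mu))
        i = j
    if want_derivs:
        return ll, grad, hess
    return ll, None, None


# ----------------------------------------------------------------------
# Cox fitter
# ----------------------------------------------------------------------

class CoxPH(BaseEstimator):
    """Cox proportional-hazards model via Newton-Raphson with step-halving.

    Convergence: gradient max-norm < ``tol`` (default 1e-8) within
    ``maxiter`` Newton iterations.  Standard errors come from the inverse
    observed information; hazard ratios are exp(beta) with Wald 95% CIs on
    the log scale.
    """

    def __init__(self, tol: float = 1e-8, maxiter: int = 100):
        self.tol = tol
        self.maxiter = maxiter

    def fit(self, surv: pd.DataFrame, covariates: list[str] | None = None,
            X: np.ndarray | None = None) -> "CoxPH":
        if X is None:
            if covariates is None:
                raise ValueError("give covariate column names or a design matrix")
            X = surv[covariates].to_numpy(dtype=float)
            names = list(covariates)
        else:
            X = np.asarray(X, dtype=float)
            names = covariates if covariates is not None else [
                f"x{i}" for i in range(X.shape[1])
            ]
        t, d = _surv_arrays(surv)
        if d.sum() < 1:
            raise ValueError("no events in the survival table")
        if X.shape[1]:
            Xc = X - X.mean(axis=0)
            R = np.linalg.qr(Xc, mode="r")
            diag = np.abs(np.diag(R))
            small = diag < 1e-8 * max(diag.max(), 1.0)
            if small.any():
                bad = [names[j] for j in np.where(small)[0]]
                raise ValueError(f"design matrix is rank deficient (columns {bad})")

        beta = np.zeros(X.shape[1])
        ll, grad, hess = _pll_grad_hess(beta, surv, X, want_derivs=True)
        converged = X.shape[1] == 0
        it = 0
        for it in range(1, self.maxiter + 1) if X.shape[1] else ():
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            step = np.linalg.solve(-hess, grad)
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                ll_new, g_new, h_new = _pll_grad_hess(cand, surv, X, want_derivs=True)
                if ll_new >= ll - 1e-12:
                    break
                scale *= 0.5
            else:
                break
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
        else:
            it = self.maxiter
        if not converged and np.max(np.abs(grad)) >= self.tol:
            raise ConvergenceError(
                "Newton-Raphson did not converge; the partial likelihood may be "
                "monotone (perfect separation)"
            )
        if X.shape[1] and np.max(np.abs(beta)) > 15.0:
            # the gradient also vanishes along a monotone likelihood; a huge
            # coefficient is the practical signature of perfect separation
            raise ConvergenceError(
                "coefficient diverged (|beta| > 15): monotone partial "
                "likelihood, most likely perfect separation"
            )

        cov = np.linalg.inv(-hess) if X.shape[1] else np.zeros((0, 0))
        se = np.sqrt(np.diag(cov))
        self.names_ = names
        self.beta_ = pd.Series(beta, index=names)
        self.se_ = pd.Series(se, index=names)
        self.cov_ = cov
        self.loglik_ = float(ll)
        self.converged_ = True
        self.n_iter_ = it
        self.n_ = len(t)
        self.n_events_ = int(d.sum())
        self.df_ = X.shape[1]
        self._surv = surv[["observed_time_h", "event"]].reset_index(drop=True)
        self._X = X
        return self

    @property
    def hazard_ratios_(self) -> pd.Series:
        check_is_fitted(self, "beta_")
        return np.exp(self.beta_)

    def confidence_intervals_(self, alpha: float = 0.05) -> pd.DataFrame:
        check_is_fitted(self, "beta_")
        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "hr_lower": np.exp(self.beta_ - z * self.se_),
                "hr_upper": np.exp(self.beta_ + z * self.se_),
            }
        )

    def baseline_cumulative_hazard(self) -> pd.DataFrame:
        """Breslow estimator of the cumulative baseline hazard (step function)."""
        check_is_fitted(self, "beta_")
        t, d = _surv_arrays(self._surv)
        eta = self._X @ self.beta_.to_numpy()
        w = np.exp(eta)
        event_times = np.unique(t[d == 1])
        incr = []
        for et in event_times:
            m = np.sum((t == et) & (d == 1))
            s0 = np.sum(w[t >= et])
            incr.append(m / s0)
        return pd.DataFrame(
            {"time_h": event_times, "cumhaz": np.cumsum(incr), "increment": incr}
        )


def cox_fit(
    surv: pd.DataFrame, covariates: list[str] | None = None, X=None, **kwargs
) -> CoxPH:
    """Fit a Cox model on a survival table; thin wrapper over :class:`CoxPH`."""
    return CoxPH(**kwargs).fit(surv, covariates=covariates, X=X)


def breslow_cumhaz(fit: CoxPH) -> pd.DataFrame:
    return fit.baseline_cumulative_hazard()


def wald_table(names, beta, se) -> pd.DataFrame:
    """Coefficient table: beta, SE, HR = exp(beta), Wald 95% CI and p."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.where(beta == 0.0, 0.0, np.inf))
    p = 2.0 * norm.sf(np.abs(z))
    zq = norm.ppf(0.975)
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "hr": np.exp(beta),
            "hr_lower": np.exp(beta - zq * se),
            "hr_upper": np.exp(beta + zq * se),
            "p": p,
        },
        index=pd.Index(names, name="term"),
    )


def hazard_ratio_table(fit: CoxPH) -> pd.DataFrame:
    """Table 1-style summary of a converged Cox fit."""
    check_is_fitted(fit, "beta_")
    return wald_table(fit.names_, fit.beta_.to_numpy(), fit.se_.to_numpy())
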