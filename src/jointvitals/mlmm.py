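"""Multivariate linear mixed model fitted by exact maximum likelihood.

Each outcome k follows y_ik(t) = x_k(t)'beta_k + b_ik0 + b_ik1 * visit + eps,
with one 2K-dimensional random-effect vector b_i ~ N(0, D) per subject
coupling the K outcomes, and independent residuals with SD sigma_k.  The
marginal likelihood is the closed-form multivariate normal with covariance
V_i = Z_i D Z_i' + diag(sigma^2); no numerical integration is involved.
Evaluation uses the Woodbury identity, so cost is linear in the number of
measurements per subject.

Estimation profiles the fixed effects out by generalized least squares and
maximizes over (log-Cholesky of D, log sigma) by quasi-Newton; standard
errors come from the inverse numeric observed information of the full
likelihood.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import norm

from .base import BaseEstimator, check_is_fitted
from .data import OUTCOMES, CohortDataset
from .design import Formulas, Prepared, PreparedSubject, formulas_from_params, prepare
from .numdiff import covariance_from_neg_hessian, numeric_hessian
from .params import (
    K,
    MLMMParams,
    logchol_factor,
    logchol_pack,
    logchol_unpack,
    n_logchol,
    visit_index,
)

_LOG2PI = np.log(2.0 * np.pi)


# ----------------------------------------------------------------------
# likelihood kernels (Woodbury, batched over shared observation patterns)
# ----------------------------------------------------------------------

class _Batch:
    """Subjects sharing one observation pattern (same Z and outcome rows),
    stacked for vectorized likelihood evaluation."""

    __slots__ = ("Z", "k_row", "X", "y")

    def __init__(self, Z, k_row, X, y):
        self.Z, self.k_row, self.X, self.y = Z, k_row, X, y


def _batches(prepared: Prepared) -> list[_Batch]:
    cached = getattr(prepared, "_mlmm_batches", None)
    if cached is not None:
        return cached
    groups: dict = {}
    for sub in prepared.subjects:
        if len(sub.y) == 0:
            continue
        key = (sub.k_row.tobytes(), sub.visit.tobytes())
        groups.setdefault(key, []).append(sub)
    out = []
    for subs in groups.values():
        out.append(
            _Batch(
                subs[0].Z,
                subs[0].k_row,
                np.stack([s.X for s in subs]),
                np.stack([s.y for s in subs]),
            )
        )
    prepared._mlmm_batches = out
    return out


def _batch_V(bt: _Batch, D, sigma):
    """Marginal covariance V = diag(sigma^2) + Z D Z' shared by the batch.

    Direct Cholesky of V stays well conditioned even when D is singular
    (boundary ML estimates are legitimate here), unlike Woodbury updates
    through D^-1.
    """
    V = bt.Z @ D @ bt.Z.T
    V[np.diag_indices_from(V)] += sigma[bt.k_row] ** 2
    cf = cho_factor(V, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return cf, logdet


def _loglik_at(prepared: Prepared, beta_vec, D, sigma) -> float:
    total = 0.0
    for bt in _batches(prepared):
        cf, logdet = _batch_V(bt, D, sigma)
        R = bt.y - bt.X @ beta_vec  # (G, m)
        G, m = R.shape
        Rsol = cho_solve(cf, R.T)  # (m, G) = V^-1 r
        quad = float(np.einsum("gm,mg->", R, Rsol))
        total += -0.5 * (G * m * _LOG2PI + G * logdet + quad)
    return total


def _profiled(prepared: Prepared, D, sigma):
    """(profiled loglik, GLS beta, information A = sum X'V^-1 X)."""
    p = prepared.p_beta
    A = np.zeros((p, p))
    c = np.zeros(p)
    q = 0.0
    logdets = 0.0
    n_tot = 0
    for bt in _batches(prepared):
        cf, logdet = _batch_V(bt, D, sigma)
        X, y = bt.X, bt.y
        G, m, _ = X.shape
        # half-solves against the shared Cholesky factor
        L = cf[0]
        W = solve_triangular(L, X.transpose(1, 0, 2).reshape(m, -1), lower=True)
        W = W.reshape(m, G, p)
        v = solve_triangular(L, y.T, lower=True)  # (m, G)
        A += np.einsum("mgp,mgq->pq", W, W)
        c += np.einsum("mgp,mg->p", W, v)
        q += float(np.einsum("mg,mg->", v, v))
        logdets += G * logdet
        n_tot += G * m
    beta = np.linalg.solve(A, c)
    ll = -0.5 * (n_tot * _LOG2PI + logdets + q - c @ beta)
    return ll, beta, A


def _profiled_grad(prepared: Prepared, theta, L_chol, sigma, beta_vec):
    """Analytic gradient of the profiled log-likelihood in theta =
    (log-Cholesky of D, log sigma).

    Uses the envelope theorem (the beta gradient vanishes at the GLS
    profile) and dl/dD = -1/2 sum_i [Z'V^-1 Z - (Z'V^-1 r)(Z'V^-1 r)'].
    """
    D = L_chol @ L_chol.T
    d = D.shape[0]
    G_D = np.zeros((d, d))
    g_s2 = np.zeros(K)  # dl/d sigma^2_k
    for bt in _batches(prepared):
        Z = bt.Z
        R = bt.y - bt.X @ beta_vec
        G, m = R.shape
        cf, _ = _batch_V(bt, D, sigma)
        Vinv = cho_solve(cf, np.eye(m))
        VinvZ = Vinv @ Z
        ZVZ = Z.T @ VinvZ
        ZVr = R @ VinvZ  # (G, d)
        G_D += -0.5 * (G * ZVZ - ZVr.T @ ZVr)
        # residual-variance pieces
        diagV = np.diag(Vinv)
        Vr = R @ Vinv  # (G, m) rows of V^-1 r
        for k_idx in range(K):
            mask = bt.k_row == k_idx
            if not mask.any():
                continue
            g_s2[k_idx] += -0.5 * (
                G * diagV[mask].sum() - np.sum(Vr[:, mask] ** 2)
            )
    # chain rule to the log-Cholesky coordinates
    GL = 2.0 * G_D @ L_chol
    grad = np.empty_like(theta)
    idx = 0
    for i in range(d):
        for j in range(i + 1):
            grad[idx] = GL[i, i] * L_chol[i, i] if i == j else GL[i, j]
            idx += 1
    grad[idx : idx + K] = g_s2 * 2.0 * sigma**2
    return grad


def marginal_loglik_mlmm(
    params: MLMMParams, dataset: CohortDataset, prepared: Prepared | None = None
) -> float:
    """Exact marginal log-likelihood of the MLMM at the given parameters."""
    if prepared is None:
        prepared = prepare(dataset, formulas_from_params(params))
    beta_vec = prepared.pack_beta(params.beta)
    return _loglik_at(prepared, beta_vec, params.D, params.sigma)


# ----------------------------------------------------------------------
# estimator
# ----------------------------------------------------------------------

class MultivariateLMM(BaseEstimator):
    """ML estimator of the multivariate linear mixed model.

    Parameters
    ----------
    formulas : dict mapping outcome code to a list of expanded baseline
        design columns; an intercept and the visit index are always included.
        Default: intercept + visit for each outcome present in the data.
    tol : relative log-likelihood convergence tolerance.
    maxiter : maximum quasi-Newton iterations.
    compute_se : whether to compute observed-information standard errors
        after convergence (numeric Hessian; skip for speed in inner loops).
    """

    def __init__(
        self,
        formulas: Formulas | None = None,
        tol: float = 1e-10,
        maxiter: int = 500,
        compute_se: bool = True,
    ):
        self.formulas = formulas
        self.tol = tol
        self.maxiter = maxiter
        self.compute_se = compute_se

    # -- internals ------------------------------------------------------
    def _theta_split(self, theta):
        nD = n_logchol(2 * K)
        D = logchol_unpack(theta[:nD], 2 * K)
        sigma = np.exp(theta[nD : nD + K])
        return D, sigma

    def _start(self, prepared: Prepared) -> np.ndarray:
        # per-outcome OLS for residual scale; between-subject spread of mean
        # residuals seeds the intercept variances
        d0 = np.empty(2 * K)
        s0 = np.empty(K)
        for k_idx in range(K):
            ys, resids, subj_means = [], [], []
            rows_X, rows_y = [], []
            for sub in prepared.subjects:
                m = sub.k_row == k_idx
                if not m.any():
                    continue
                rows_X.append(np.column_stack([sub.X[m], sub.Z[m, 2 * k_idx + 1]]))
                rows_y.append(sub.y[m])
            if not rows_X:
                s0[k_idx] = 1.0
                d0[2 * k_idx : 2 * k_idx + 2] = (1.0, 0.1)
                continue
            Xall = np.vstack(rows_X)
            yall = np.concatenate(rows_y)
            coef, *_ = np.linalg.lstsq(Xall, yall, rcond=None)
            rall = yall - Xall @ coef
            i = 0
            for sub in prepared.subjects:
                m = sub.k_row == k_idx
                if m.any():
                    subj_means.append(np.mean(rall[i : i + m.sum()]))
                    i += m.sum()
            s2 = max(np.var(rall), 1e-4)
            v_int = max(np.var(subj_means), 0.1 * s2)
            s0[k_idx] = np.sqrt(max(s2 - v_int, 0.25 * s2))
            d0[2 * k_idx] = v_int
            d0[2 * k_idx + 1] = max(0.01 * v_int, 1e-3)
        theta0 = np.concatenate([logchol_pack(np.diag(d0)), np.log(s0)])
        return theta0

    # -- API --------------------------------------------------------------
    def fit(self, dataset: CohortDataset, start: MLMMParams | None = None):
        formulas = self.formulas
        if formulas is None:
            present = [k for k in OUTCOMES if k in set(dataset.longitudinal["outcome"])]
            formulas = {k: [] for k in present}
        prepared = prepare(dataset, formulas)
        for sub in prepared.subjects:
            counts = np.bincount(sub.k_row, minlength=K)
            needed = [i for i, k in enumerate(OUTCOMES) if k in formulas]
            if any(counts[i] == 0 for i in needed):
                raise ValueError(
                    f"subject {sub.subject_id} lacks observations for a modeled outcome"
                )

        nD = n_logchol(2 * K)
        if start is not None:
            theta0 = np.concatenate(
                [logchol_pack(start.D), np.log(start.sigma)]
            )
        else:
            theta0 = self._start(prepared)

        def negll_grad(theta):
            L = logchol_factor(theta[:nD], 2 * K)
            D = L @ L.T
            sigma = np.exp(theta[nD : nD + K])
            try:
                ll, beta_vec, _ = _profiled(prepared, D, sigma)
            except np.linalg.LinAlgError:
                return 1e12, np.zeros_like(theta)
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(theta)
            grad = _profiled_grad(prepared, theta, L, sigma, beta_vec)
            return -ll, -grad

        res = optimize.minimize(
            negll_grad,
            theta0,
            method="L-BFGS-B",
            jac=True,
            options={
                "maxiter": self.maxiter,
                "ftol": self.tol,
                "gtol": 1e-7,
                "maxfun": 200000,
            },
        )
        D, sigma = self._theta_split(res.x)
        ll, beta_vec, A = _profiled(prepared, D, sigma)
        L_fin = logchol_factor(res.x[:nD], 2 * K)
        g_fin = _profiled_grad(prepared, res.x, L_fin, sigma, beta_vec)

        self.prepared_ = prepared
        self.dataset_ = dataset
        self.params_ = MLMMParams(prepared.unpack_beta(beta_vec), D, sigma, check=False)
        self.loglik_ = float(ll)
        # iteration caps while grinding along a variance boundary still count
        # as converged when the score has effectively vanished
        self.converged_ = bool(res.success) or (
            np.max(np.abs(g_fin)) < 1e-4 * max(1.0, abs(ll))
        )
        self.n_iter_ = int(res.nit)
        self.df_ = prepared.p_beta + nD + K
        self.n_ = prepared.n
        self.theta_ = res.x.copy()
        self.message_ = res.message

        if self.compute_se:
            self._compute_se(prepared, beta_vec, res.x)
        else:
            # GLS information for the fixed effects (exact beta block)
            d = np.diag(np.linalg.inv(A)).copy()
            d[d < 0] = np.nan
            se = np.sqrt(d)
            self.se_beta_ = pd.Series(
                se, index=pd.MultiIndex.from_tuples(prepared.beta_names)
            )
            self.cov_ = None
        self.beta_vec_ = beta_vec
        return self

    def _compute_se(self, prepared, beta_vec, theta):
        full0 = np.concatenate([beta_vec, theta])
        p_beta = prepared.p_beta

        def negll_full(x):
            D, sigma = self._theta_split(x[p_beta:])
            return -_loglik_at(prepared, x[:p_beta], D, sigma)

        H = numeric_hessian(negll_full, full0, step=1e-4)
        cov = covariance_from_neg_hessian(H)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        se = np.sqrt(d)
        self.cov_ = cov
        self.se_beta_ = pd.Series(
            se[:p_beta], index=pd.MultiIndex.from_tuples(prepared.beta_names)
        )
        nD = n_logchol(2 * K)
        # delta method: se(sigma) = sigma * se(log sigma)
        self.se_sigma_ = self.params_.sigma * se[p_beta + nD : p_beta + nD + K]

    # -- post-fit quantities ---------------------------------------------
    def blup(self) -> tuple[pd.DataFrame, list[np.ndarray]]:
        """Posterior means and covariances of the random effects.

        Mean D Z'V^-1 (y - X beta), covariance D - D Z'V^-1 Z D; a subject
        with no data gets mean 0 and covariance D.
        """
        check_is_fitted(self, "params_")
        D, sigma = self.params_.D, self.params_.sigma
        means, covs, ids = [], [], []
        for sub in self.prepared_.subjects:
            ids.append(sub.subject_id)
            if len(sub.y) == 0:
                means.append(np.zeros(2 * K))
                covs.append(D.copy())
                continue
            r = sub.y - sub.X @ self.beta_vec_
            V = sub.Z @ D @ sub.Z.T
            V[np.diag_indices_from(V)] += sigma[sub.k_row] ** 2
            cf = cho_factor(V, lower=True)
            DZ = D @ sub.Z.T  # (2K, m)
            means.append(DZ @ cho_solve(cf, r))
            covs.append(D - DZ @ cho_solve(cf, DZ.T))
        cols = [f"{k}_{w}" for k in OUTCOMES for w in ("intercept", "slope")]
        return (
            pd.DataFrame(means, index=pd.Index(ids, name="subject_id"), columns=cols),
            covs,
        )

    def predict_trajectory(
        self, subject_id: str, outcome: str, times_h: np.ndarray
    ) -> np.ndarray:
        """Subject-specific prediction x(t)'beta + z(t)'BLUP at given hours.

        An unknown subject triggers a warning and yields the population-level
        prediction at reference covariates.
        """
        check_is_fitted(self, "params_")
        k_idx = OUTCOMES.index(outcome)
        beta = self.params_.beta[outcome]
        v = visit_index(np.asarray(times_h, dtype=float))
        sub = next(
            (s for s in self.prepared_.subjects if s.subject_id == subject_id), None
        )
        if sub is None:
            warnings.warn(
                f"subject {subject_id!r} unknown; returning population prediction"
            )
            fixed = beta.iloc[0] + beta.iloc[1] * v
            return np.asarray(fixed)
        x0 = sub.x0[outcome]
        const = float(x0 @ beta.to_numpy())
        bl, _ = self.blup()
        b = bl.loc[subject_id].to_numpy()
        return const + beta.iloc[1] * v + b[2 * k_idx] + b[2 * k_idx + 1] * v

    def residuals(self, standardized: bool = True) -> pd.DataFrame:
        """Conditional residuals y - x'beta - z'BLUP (optionally / sigma_k)."""
        check_is_fitted(self, "params_")
        bl, _ = self.blup()
        rows = []
        for sub in self.prepared_.subjects:
            if len(sub.y) == 0:
                continue
            b = bl.loc[sub.subject_id].to_numpy()
            r = sub.y - sub.X @ self.beta_vec_ - sub.Z @ b
            if standardized:
                r = r / self.params_.sigma[sub.k_row]
            for k_idx, val in zip(sub.k_row, r):
                rows.append((sub.subject_id, OUTCOMES[k_idx], float(val)))
        return pd.DataFrame(rows, columns=["subject_id", "outcome", "residual"])

    def summary(self) -> pd.DataFrame:
        """Fixed-effect table: estimate, SE, Wald z and p per coefficient."""
        check_is_fitted(self, "params_")
        est = pd.Series(
            self.beta_vec_,
            index=pd.MultiIndex.from_tuples(
                self.prepared_.beta_names, names=["outcome", "term"]
            ),
        )
        se = self.se_beta_.to_numpy()
        z = est.to_numpy() / se
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": est.to_numpy(), "se": se, "z": z, "p": p}, index=est.index
        )


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------

def mlmm_fit(
    dataset: CohortDataset,
    formulas: Formulas | None = None,
    compute_se: bool = True,
    **kwargs,
) -> MultivariateLMM:
    """Fit the MLMM and return the fitted estimator."""
    return MultivariateLMM(formulas=formulas, compute_se=compute_se, **kwargs).fit(
        dataset
    )


def blup_random_effects(fit: MultivariateLMM):
    return fit.blup()


def predict_trajectory(fit: MultivariateLMM, subject_id, outcome, times_h):
    return fit.predict_trajectory(subject_id, outcome, times_h)


def qq_points(residuals) -> tuple[np.ndarray, np.ndarray]:
    """Normal QQ pairs: theoretical quantiles at (i - 0.5)/n vs order stats."""
    r = np.sort(np.asarray(residuals, dtype=float))
    n = len(r)
    if n < 2:
        raise ValueError("need at least two residuals")
    probs = (np.arange(1, n + 1) - 0.5) / n
    return norm.ppf(probs), r
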