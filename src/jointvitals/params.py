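"""Parameter containers shared by the longitudinal, survival and joint models.

Random-effect layout: each subject carries a 2K-vector b ordered as
(RR intercept, RR slope, PR intercept, PR slope, OX intercept, OX slope),
i.e. a random intercept and a random per-visit slope per outcome, with one
2K x 2K covariance D coupling everything.  The longitudinal time covariate is
the visit index t/6 (visits are scheduled every 6 h), so slopes are per visit.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field, replace

import numpy as np
import pandas as pd

from .data import OUTCOMES, VISIT_SPACING_H

K = len(OUTCOMES)

INTERCEPT = "Intercept"
VISIT = "visit"


def _as_series(v, name: str) -> pd.Series:
    s = pd.Series(v, dtype=float)
    s.name = name
    return s


@dataclass
class MLMMParams:
    """Parameters of the multivariate linear mixed model.

    beta maps each outcome code to a named coefficient vector whose index
    starts with (Intercept, visit) followed by baseline-covariate design
    columns; D is the 2K x 2K random-effect covariance; sigma holds the K
    residual standard deviations.  ``check=False`` skips the invariant
    checks (used internally where validity is guaranteed by construction,
    e.g. log-Cholesky unpacking near a boundary optimum).
    """

    beta: dict[str, pd.Series]
    D: np.ndarray
    sigma: np.ndarray
    check: InitVar[bool] = True

    def __post_init__(self, check: bool = True) -> None:
        self.beta = {k: _as_series(v, k) for k, v in self.beta.items()}
        self.D = np.asarray(self.D, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.D.shape != (2 * K, 2 * K):
            raise ValueError(f"D must be {2*K}x{2*K}")
        if not check:
            return
        if not np.allclose(self.D, self.D.T):
            raise ValueError("D must be symmetric")
        if np.any(np.linalg.eigvalsh(self.D) <= 0):
            raise ValueError("D must be positive definite")
        if self.sigma.shape != (K,) or np.any(self.sigma <= 0):
            raise ValueError("sigma must be K positive residual SDs")
        for k in self.beta:
            if k not in OUTCOMES:
                raise ValueError(f"unknown outcome {k!r}")

    @property
    def outcomes(self) -> list[str]:
        return [k for k in OUTCOMES if k in self.beta]

    def copy(self) -> "MLMMParams":
        return MLMMParams(
            {k: v.copy() for k, v in self.beta.items()},
            self.D.copy(),
            self.sigma.copy(),
            check=False,
        )


@dataclass
class JointParams:
    """Joint-model parameters: MLMM block, survival coefficients zeta,
    association vector gamma and a piecewise-constant log baseline hazard.

    knots s_0 < ... < s_B delimit B intervals; hazard is zero before s_0 and
    the last height extends beyond s_B.  gamma[k] multiplies the current value
    m_ik(t) of outcome k in the log recovery hazard.
    """

    mlmm: MLMMParams
    zeta: pd.Series
    gamma: np.ndarray
    knots: np.ndarray
    log_lambda: np.ndarray

    def __post_init__(self) -> None:
        self.zeta = _as_series(self.zeta, "zeta")
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.knots = np.asarray(self.knots, dtype=float)
        self.log_lambda = np.asarray(self.log_lambda, dtype=float)
        if self.gamma.shape != (K,):
            raise ValueError("gamma must have length K")
        if np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        if len(self.log_lambda) != len(self.knots) - 1 or len(self.log_lambda) < 1:
            raise ValueError("need B >= 1 heights for B+1 knots")

    @property
    def heights(self) -> np.ndarray:
        return np.exp(self.log_lambda)

    def with_heights_scaled(self, factor: float) -> "JointParams":
        return replace(
            self,
            mlmm=self.mlmm.copy(),
            zeta=self.zeta.copy(),
            gamma=self.gamma.copy(),
            knots=self.knots.copy(),
            log_lambda=self.log_lambda + np.log(factor),
        )

    def copy(self) -> "JointParams":
        return self.with_heights_scaled(1.0)


# ----------------------------------------------------------------------
# log-Cholesky packing of a covariance matrix (unconstrained <-> SPD)
# ----------------------------------------------------------------------

def logchol_pack(D: np.ndarray) -> np.ndarray:
    """Lower-triangular Cholesky factor of D, flattened row-wise with the
    diagonal on the log scale.

    Near-singular D (legitimate boundary estimates) gets a minimal
    eigenvalue lift so the factorization exists.
    """
    try:
        L = np.linalg.cholesky(D)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh((D + D.T) / 2.0)
        w = np.maximum(w, 1e-10 * max(w.max(), 1.0))
        L = np.linalg.cholesky(V @ np.diag(w) @ V.T)
    d = L.shape[0]
    out = []
    for i in range(d):
        for j in range(i + 1):
            out.append(np.log(L[i, i]) if i == j else L[i, j])
    return np.array(out)


def logchol_factor(theta: np.ndarray, d: int) -> np.ndarray:
    """Lower-triangular Cholesky factor encoded by theta."""
    L = np.zeros((d, d))
    idx = 0
    for i in range(d):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[idx]) if i == j else theta[idx]
            idx += 1
    return L


def logchol_unpack(theta: np.ndarray, d: int) -> np.ndarray:
    """Inverse of :func:`logchol_pack`; always returns a symmetric PD matrix."""
    L = logchol_factor(theta, d)
    return L @ L.T


def n_logchol(d: int) -> int:
    return d * (d + 1) // 2


def visit_index(time_h) -> np.ndarray:
    """Visit index used as the longitudinal time covariate (t / 6 h)."""
    return np.asarray(time_h, dtype=float) / VISIT_SPACING_H
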