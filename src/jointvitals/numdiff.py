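"""Finite-difference derivatives used for observed-information standard errors."""

from __future__ import annotations

import numpy as np


def numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of a scalar function.

    Steps are relative (step * max(1, |x_i|)) on the supplied scale.
    """
    x = np.asarray(x, dtype=float)
    p = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def covariance_from_neg_hessian(H: np.ndarray) -> np.ndarray:
    """Invert an observed information matrix, with a pseudo-inverse fallback
    for near-singular information."""
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)
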