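"""Closed-form piecewise-exponential hazard machinery.

Under a current-value association the subject-specific log hazard is

    log h_i(t) = log lambda_{b(t)} + eta_i + C_i * t,

with eta_i collecting every time-constant term (survival covariates zeta'x,
the association applied to intercept-level current values) and C_i the
per-hour slope of the summed association term.  The cumulative hazard over an
interval [l, u] with constant baseline height lambda is then

    lambda * exp(eta) * (exp(C u) - exp(C l)) / C,

which this module evaluates, differentiates with respect to C, and inverts
analytically.  The baseline is zero before the first knot and the last height
extends beyond the last knot.
"""

from __future__ import annotations

import numpy as np

# below this |C|*scale the series expansion of psi is used
_SMALL_C = 1e-8


def psi(C, l, u):
    """(exp(C u) - exp(C l)) / C with a stable C -> 0 limit (= u - l).

    Broadcasts over any mix of array arguments.
    """
    C, l, u = np.broadcast_arrays(*np.atleast_1d(C, l, u))
    out = np.empty(C.shape, dtype=float)
    small = np.abs(C) * np.maximum(np.abs(l), np.abs(u)) < _SMALL_C
    ns = ~small
    out[ns] = (np.exp(C[ns] * u[ns]) - np.exp(C[ns] * l[ns])) / C[ns]
    cs, ls, us = C[small], l[small], u[small]
    out[small] = (
        (us - ls)
        + cs * (us**2 - ls**2) / 2.0
        + cs**2 * (us**3 - ls**3) / 6.0
        + cs**3 * (us**4 - ls**4) / 24.0
    )
    return out


def psi_dC(C, l, u):
    """First derivative of :func:`psi` with respect to C."""
    C, l, u = np.broadcast_arrays(*np.atleast_1d(C, l, u))
    out = np.empty(C.shape, dtype=float)
    small = np.abs(C) * np.maximum(np.abs(l), np.abs(u)) < 1e-5
    ns = ~small
    p = psi(C[ns], l[ns], u[ns])
    out[ns] = (u[ns] * np.exp(C[ns] * u[ns]) - l[ns] * np.exp(C[ns] * l[ns]) - p) / C[
        ns
    ]
    cs, ls, us = C[small], l[small], u[small]
    out[small] = (
        (us**2 - ls**2) / 2.0
        + cs * (us**3 - ls**3) / 3.0
        + cs**2 * (us**4 - ls**4) / 8.0
    )
    return out


def psi_d2C(C, l, u):
    """Second derivative of :func:`psi` with respect to C."""
    C, l, u = np.broadcast_arrays(*np.atleast_1d(C, l, u))
    out = np.empty(C.shape, dtype=float)
    small = np.abs(C) * np.maximum(np.abs(l), np.abs(u)) < 1e-3
    ns = ~small
    p1 = psi_dC(C[ns], l[ns], u[ns])
    out[ns] = (
        u[ns] ** 2 * np.exp(C[ns] * u[ns])
        - l[ns] ** 2 * np.exp(C[ns] * l[ns])
        - 2.0 * p1
    ) / C[ns]
    cs, ls, us = C[small], l[small], u[small]
    out[small] = (us**3 - ls**3) / 3.0 + cs * (us**4 - ls**4) / 4.0
    return out


def interval_index(knots: np.ndarray, t):
    """Index of the baseline interval containing t (last height extended).

    Returns -1 for t below the first knot (zero hazard there).
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(knots, t, side="right") - 1
    idx = np.minimum(idx, len(knots) - 2)
    idx[t < knots[0]] = -1
    return idx


def cumulative_hazard_scalar_terms(
    knots: np.ndarray, heights: np.ndarray, eta, C, t
) -> np.ndarray:
    """Lambda(t) = sum_b lambda_b exp(eta) psi(C; l_b, u_b) over [0, t].

    Vectorized over subjects: eta, C, t are 1-d arrays of equal length.
    The last height extends beyond the last knot.
    """
    eta, C, t = np.broadcast_arrays(*np.atleast_1d(eta, C, t))
    B = len(heights)
    total = np.zeros(eta.shape, dtype=float)
    for b in range(B):
        lo = knots[b]
        hi = knots[b + 1] if b < B - 1 else np.inf
        active = t > lo
        if not np.any(active):
            continue
        uu = np.minimum(t, hi) if np.isfinite(hi) else t
        contrib = np.zeros(eta.shape)
        contrib[active] = heights[b] * np.exp(eta[active]) * psi(
            C[active], lo, uu[active]
        )
        total += contrib
    return total


def invert_cumulative_hazard(
    knots: np.ndarray, heights: np.ndarray, eta, C, target
) -> np.ndarray:
    """Smallest T with Lambda(T) = target, or inf when never reached.

    Scans the baseline intervals accumulating closed-form hazard mass and
    inverts analytically inside the bracketing interval.  Vectorized over
    subjects (eta, C, target equal-length arrays).
    """
    eta, C, target = np.broadcast_arrays(*np.atleast_1d(eta, C, target))
    n = eta.shape[0]
    T = np.full(n, np.inf)
    remaining = target.astype(float).copy()
    done = np.zeros(n, dtype=bool)
    B = len(heights)
    scale = np.exp(eta)
    for b in range(B):
        lo = knots[b]
        hi = knots[b + 1] if b < B - 1 else np.inf
        lam = heights[b] * scale
        if np.isfinite(hi):
            mass = lam * psi(C, lo, hi)
        else:
            # extended final interval: finite total mass only when C < 0
            with np.errstate(divide="ignore", invalid="ignore"):
                mass = np.where(C < 0, lam * (-np.exp(C * lo) / np.where(C < 0, C, -1.0)), np.inf)
        inside = (~done) & (remaining <= mass * (1 - 1e-15))
        if np.any(inside):
            ci, li = C[inside], lam[inside]
            r = remaining[inside]
            with np.errstate(over="ignore", invalid="ignore"):
                arg = np.exp(ci * lo) + r * ci / li
                t_in = np.where(
                    np.abs(ci) * max(abs(lo), 1.0) < _SMALL_C,
                    lo + r / li,
                    np.log(np.maximum(arg, 1e-300)) / np.where(ci == 0, 1.0, ci),
                )
            # exact C == 0 entries handled by the small-C branch above
            T[inside] = t_in
            done[inside] = True
        remaining = np.where(done, remaining, remaining - mass)
    return T
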