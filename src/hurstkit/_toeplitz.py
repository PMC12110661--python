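"""Levinson/Durbin quadratic forms for Toeplitz autocorrelation matrices.

The Bayesian HK posterior needs, for the n x n symmetric positive-definite
Toeplitz matrix R built from an autocorrelation sequence rho:

    x'R^{-1}x,  e'R^{-1}e,  e'R^{-1}x,  ln|R|        (e = vector of ones)

all in O(n^2) time and O(n) memory.  The Durbin recursion yields, at each
order t, the best-linear-predictor coefficients phi_t and the prediction
error variance v_t; the Gaussian innovations factorization then gives

    x'R^{-1}x = sum_t (x_t - phi_t . x_{<t})^2 / v_t,     ln|R| = sum_t ln v_t,

and the e-vector and cross terms follow from the same projections (the
quadratic form is bilinear in its arguments).

The hot loops are compiled with numba when available; the fallback runs the
identical algorithm in pure Python (correct, much slower).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    NUMBA = True
except ImportError:  # pragma: no cover
    NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


__all__ = ["quad_forms_raw", "hk_log_posterior_many", "NUMBA"]


@njit(cache=True, fastmath=True)
def _quad_forms_core(rho, x):
    """Return (xRx, eRe, eRx, logdet, ok) for Toeplitz R = toeplitz(rho).

    ok = 0.0 signals a numerically non-positive-definite recursion
    (prediction-error variance fell to <= 0).
    """
    n = x.shape[0]
    phi = np.zeros(n, dtype=np.float64)
    v = rho[0]
    if v <= 0.0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    qx = x[0] * x[0] / v
    qe = 1.0 / v
    qxe = x[0] / v
    logdet = np.log(v)
    for t in range(1, n):
        acc = rho[t]
        for j in range(1, t):
            acc -= phi[j - 1] * rho[t - j]
        kappa = acc / v
        # symmetric in-place order update of the predictor coefficients
        half = (t - 1) // 2
        for j in range(half):
            tmp = phi[j]
            phi[j] = tmp - kappa * phi[t - 2 - j]
            phi[t - 2 - j] -= kappa * tmp
        if (t - 1) % 2 == 1:
            phi[half] -= kappa * phi[half]
        phi[t - 1] = kappa
        v *= 1.0 - kappa * kappa
        if v <= 0.0 or not np.isfinite(v):
            return qx, qe, qxe, logdet, 0.0
        ex = x[t]
        ee = 1.0
        for j in range(1, t + 1):
            ex -= phi[j - 1] * x[t - j]
            ee -= phi[j - 1]
        qx += ex * ex / v
        qe += ee * ee / v
        qxe += ex * ee / v
        logdet += np.log(v)
    return qx, qe, qxe, logdet, 1.0


@njit(cache=True, fastmath=True)
def _logpost_core(h, x, rho, pw):
    """Unnormalized HK log-posterior of the Hurst exponent at ``h``.

    ln pi(h | x) = -1/2 ln|R| - (n-1)/2 ln(eRe*xRx - eRx^2) + (n/2 - 1) ln(eRe)

    with R the exact fGn autocorrelation matrix at Hurst exponent ``h``.
    ``rho`` and ``pw`` are scratch buffers of length n and n+1.
    Returns -inf on a numerically non-positive-definite R or bracket.
    """
    n = x.shape[0]
    two_h = 2.0 * h
    for k in range(n + 1):
        pw[k] = k**two_h
    rho[0] = 1.0
    for k in range(1, n):
        rho[k] = 0.5 * (pw[k + 1] - 2.0 * pw[k] + pw[k - 1])
    qx, qe, qxe, logdet, ok = _quad_forms_core(rho, x)
    if ok == 0.0:
        return -np.inf
    bracket = qe * qx - qxe * qxe
    if bracket <= 0.0 or qe <= 0.0:
        return -np.inf
    return -0.5 * logdet - 0.5 * (n - 1) * np.log(bracket) + (0.5 * n - 1.0) * np.log(qe)


@njit(cache=True, fastmath=True)
def _logpost_many_core(hs, x, out):
    n = x.shape[0]
    rho = np.empty(n, dtype=np.float64)
    pw = np.empty(n + 1, dtype=np.float64)
    for i in range(hs.shape[0]):
        out[i] = _logpost_core(hs[i], x, rho, pw)


def quad_forms_raw(rho: np.ndarray, x: np.ndarray):
    """Quadratic forms of toeplitz(rho); raises on non-positive-definiteness.

    Returns the tuple ``(xRx, eRe, eRx, logdetR)``.
    """
    rho = np.ascontiguousarray(rho, dtype=np.float64)
    x = np.ascontiguousarray(x, dtype=np.float64)
    if rho.shape != x.shape:
        raise ValueError(
            f"autocorrelation length {rho.shape[0]} != series length {x.shape[0]}"
        )
    qx, qe, qxe, logdet, ok = _quad_forms_core(rho, x)
    if ok == 0.0:
        raise np.linalg.LinAlgError(
            "autocorrelation matrix is numerically non-positive-definite"
        )
    return qx, qe, qxe, logdet


def hk_log_posterior_many(hs, x) -> np.ndarray:
    """Vectorized unnormalized HK log-posterior over an array of h values."""
    hs = np.ascontiguousarray(hs, dtype=np.float64)
    x = np.ascontiguousarray(x, dtype=np.float64)
    out = np.empty(hs.shape[0], dtype=np.float64)
    _logpost_many_core(hs, x, out)
    return out
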