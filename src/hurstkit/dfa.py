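"""Detrended fluctuation analysis (DFA) of first and second order.

DFA estimates the Hurst exponent from the scaling of detrended fluctuations
of the cumulative profile

    y_i = sum_{k<=i} (x_k - mean(x)).

For each bin size ``s`` the profile is cut into ``N_s = floor(n/s)``
non-overlapping windows from the start (the trailing remainder is
discarded), a polynomial of degree ``order`` (1 or 2) is fit per window by
least squares, and the fluctuation function is the RMS of the residuals
averaged over windows:

    f(s) = sqrt( (1/N_s) sum_v (1/s) sum_i residual_{v,i}^2 ).

Since f(s) ~ s^H for fractional Gaussian noise, the slope of ln f on ln s
estimates H.  The default bin sizes are the arithmetic sequence
4, 8, 12, ... up to n/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fgn import validate_series

__all__ = [
    "DFAEstimate",
    "build_profile",
    "default_scales",
    "dfa_fluctuations",
    "fit_scaling_exponent",
    "estimate_h_dfa",
]


@dataclass(frozen=True)
class DFAEstimate:
    """DFA result: bin sizes, fluctuation function, and the fitted exponent."""

    scales: np.ndarray = field(repr=False)
    fluctuations: np.ndarray = field(repr=False)
    order: int
    h_hat: float
    intercept: float


def build_profile(x) -> np.ndarray:
    """Cumulative sum of mean-centered observations (the DFA profile).

    The final profile value is zero up to rounding (telescoping sum).
    """
    x = validate_series(x)
    return np.cumsum(x - x.mean())


def default_scales(n: int) -> np.ndarray:
    """Arithmetic bin sizes 4, 8, 12, ... up to n/2 (needs n >= 16)."""
    n = int(n)
    if n < 16:
        raise ValueError(f"too short for two DFA scales: n={n} < 16")
    return np.arange(4, n // 2 + 1, 4)


def _validate_scales(scales, n: int) -> np.ndarray:
    scales = np.asarray(scales, dtype=int)
    if scales.ndim != 1 or len(scales) < 2:
        raise ValueError("need at least 2 scales")
    if np.any(np.diff(scales) <= 0):
        raise ValueError("scales must be strictly increasing")
    if scales[0] < 4:
        raise ValueError(f"smallest scale must be >= 4; got {scales[0]}")
    if scales[-1] > n // 2:
        raise ValueError(f"largest scale {scales[-1]} exceeds n/2 = {n // 2}")
    return scales


def dfa_fluctuations(y, scales, order: int) -> np.ndarray:
    """Fluctuation function f(s) of a profile for the given bin sizes.

    Windows are taken from the start of the profile only; the remainder
    beyond ``floor(n/s) * s`` is discarded.  Polynomial fits use the
    within-window index centered at zero (identical residuals, better
    conditioning).
    """
    y = np.asarray(y, dtype=float)
    if order not in (1, 2):
        raise ValueError(f"detrending order must be 1 or 2; got {order}")
    n = len(y)
    scales = np.asarray(scales, dtype=int)
    fl = np.empty(len(scales))
    for j, s in enumerate(scales):
        n_windows = n // s
        if n_windows < 1:
            raise ValueError(f"scale {s} exceeds profile length {n}")
        windows = y[: n_windows * s].reshape(n_windows, s)
        t = np.arange(1.0, s + 1.0)
        design = np.vander(t - t.mean(), order + 1, increasing=True)
        q, _ = np.linalg.qr(design)
        resid = windows - (windows @ q) @ q.T
        fl[j] = np.sqrt(np.mean(resid**2))
    return fl


def fit_scaling_exponent(scales, fluctuations) -> tuple[float, float]:
    """Least-squares slope and intercept of ln f(s) on ln s."""
    scales = np.asarray(scales, dtype=float)
    fluctuations = np.asarray(fluctuations, dtype=float)
    if len(scales) < 2:
        raise ValueError("need at least 2 scales to fit a slope")
    if np.any(fluctuations <= 0.0):
        raise ValueError("degenerate fluctuation: f(s) must be positive at every scale")
    slope, intercept = np.polyfit(np.log(scales), np.log(fluctuations), 1)
    return float(slope), float(intercept)


def estimate_h_dfa(x, order: int = 1, scales=None) -> DFAEstimate:
    """Full DFA pipeline: profile, fluctuation function, log-log fit.

    Parameters
    ----------
    x : array-like
        Series of length >= 16.
    order : {1, 2}
        Polynomial detrending order (DFA1 or DFA2).
    scales : array-like of int, optional
        Override for the default bin sizes 4, 8, 12, ... <= n/2.

    Returns
    -------
    DFAEstimate
        ``h_hat`` is the fitted scaling exponent.  Deterministic.
    """
    x = validate_series(x, min_length=16)
    scales = default_scales(len(x)) if scales is None else _validate_scales(scales, len(x))
    y = build_profile(x)
    fl = dfa_fluctuations(y, scales, order)
    h_hat, intercept = fit_scaling_exponent(scales, fl)
    return DFAEstimate(
        scales=scales, fluctuations=fl, order=int(order), h_hat=h_hat, intercept=intercept
    )
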