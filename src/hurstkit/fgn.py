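"""Exact fractional Gaussian noise: autocorrelation and circulant-embedding simulation.

Fractional Gaussian noise (fGn) is the stationary Gaussian process whose
lag-``k`` autocorrelation is

.. math::

    \\rho_k = \\tfrac{1}{2}\\left(|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}\\right),

with Hurst exponent ``H`` in (0, 1).  ``H < 0.5`` gives anti-persistent
(negatively correlated) noise, ``H = 0.5`` white noise, and ``H > 0.5``
persistent noise with slowly decaying positive correlations.

Simulation uses the Davies--Harte circulant-embedding construction: the
n x n Toeplitz covariance is embedded in a circulant matrix of size
``2(n - 1)`` which the discrete Fourier transform diagonalizes, giving an
*exact* Gaussian sample (zero mean, unit variance, the autocovariance above)
in O(n log n) time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FGnAcf", "fgn_acf", "simulate_fgn", "validate_series"]

#: minimum admissible series length across the package
MIN_LENGTH = 8


def _check_hurst(H: float) -> float:
    H = float(H)
    if not 0.0 < H < 1.0:
        raise ValueError(f"Hurst exponent must lie in the open interval (0, 1); got {H}")
    return H


def validate_series(x, min_length: int = MIN_LENGTH) -> np.ndarray:
    """Coerce ``x`` to a 1-D float array and enforce the series invariants.

    Parameters
    ----------
    x : array-like
        Ordered real observations.
    min_length : int
        Minimum admissible length (default 8).

    Returns
    -------
    numpy.ndarray
        1-D float64 view/copy of ``x``.
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"time series must be one-dimensional; got shape {arr.shape}")
    if arr.size < min_length:
        raise ValueError(f"time series too short: n={arr.size} < {min_length}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("time series contains non-finite values")
    return arr


@dataclass(frozen=True)
class FGnAcf:
    """Exact fGn autocorrelation sequence ``rho[0..max_lag]`` for a given H."""

    H: float
    rho: np.ndarray = field(repr=False)

    @property
    def max_lag(self) -> int:
        return len(self.rho) - 1


def fgn_acf(H: float, max_lag: int) -> FGnAcf:
    """Exact finite-lag fGn autocorrelation function.

    Evaluates ``rho_k = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2`` for
    ``k = 0..max_lag`` (the exact form, not the asymptotic power law).

    Parameters
    ----------
    H : float
        Hurst exponent, strictly inside (0, 1).
    max_lag : int
        Largest lag to evaluate (>= 0).

    Returns
    -------
    FGnAcf
        ``rho[0] == 1`` always; for ``k >= 1`` the sign of ``rho_k`` equals
        the sign of ``H - 0.5``.
    """
    H = _check_hurst(H)
    max_lag = int(max_lag)
    if max_lag < 0:
        raise ValueError(f"max_lag must be nonnegative; got {max_lag}")
    k = np.arange(max_lag + 1, dtype=float)
    two_h = 2.0 * H
    rho = 0.5 * (np.abs(k + 1) ** two_h - 2.0 * k**two_h + np.abs(k - 1) ** two_h)
    rho[0] = 1.0
    return FGnAcf(H=H, rho=rho)


def circulant_eigenvalues(H: float, n: int) -> np.ndarray:
    """Eigenvalues of the size-``2(n-1)`` circulant embedding of the fGn covariance.

    Exposed for inspection; :func:`simulate_fgn` errors if any is negative.
    """
    n = int(n)
    if n < MIN_LENGTH:
        raise ValueError(f"series length must be >= {MIN_LENGTH}; got {n}")
    rho = fgn_acf(H, n - 1).rho
    # first row of the circulant: rho_0..rho_{n-1}, rho_{n-2}..rho_1
    c = np.concatenate([rho, rho[-2:0:-1]])
    return np.fft.rfft(c).real


def simulate_fgn(H: float, n: int, seed) -> np.ndarray:
    """Draw one exact fGn sample path of length ``n``.

    Davies--Harte synthesis: the circulant spectrum ``lam_k`` (k = 0..m/2,
    m = 2(n-1)) scales complex Gaussian Fourier coefficients; the inverse
    real FFT returns a real Gaussian vector whose first ``n`` entries have
    exactly the fGn autocovariance.  The sample has population mean 0 and
    population variance 1; no empirical standardization is applied.

    The RNG stream is consumed in a fixed, documented order: ``m`` standard
    normal draws laid out by frequency — draw 0 for the zero frequency, then
    for each positive frequency k the real part before the imaginary part,
    and the final draw for the Nyquist frequency.

    Parameters
    ----------
    H : float
        Hurst exponent in (0, 1).
    n : int
        Series length, >= 8.
    seed : int or numpy.random.SeedSequence or numpy.random.Generator
        Source of randomness; identical seeds give bit-identical output.

    Raises
    ------
    FloatingPointError
        If the circulant spectrum has a negative eigenvalue for this
        ``(H, n)`` (never silently clipped).
    """
    n = int(n)
    lam = circulant_eigenvalues(H, n)  # validates H and n
    if np.any(lam < 0.0):
        raise FloatingPointError(
            f"circulant embedding has a negative eigenvalue for H={H}, n={n}: "
            f"min eigenvalue {lam.min():.3e}"
        )
    m = 2 * (n - 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.standard_normal(m)

    a = np.empty(n, dtype=complex)  # half spectrum, k = 0..m/2
    a[0] = np.sqrt(lam[0] / m) * z[0]
    interior = np.sqrt(lam[1:-1] / (2.0 * m))
    a[1:-1] = interior * (z[1 : m - 1 : 2] + 1j * z[2 : m - 1 : 2])
    a[-1] = np.sqrt(lam[-1] / m) * z[m - 1]

    x = np.fft.irfft(a, m) * m
    return x[:n]
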