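"""Bayesian Hurst--Kolmogorov (HK) estimator of the Hurst exponent.

The HK method treats the observed series as fractional Gaussian noise and
samples the Hurst exponent H from its marginal posterior (location and scale
integrated out under noninformative priors).  Up to an additive constant,

    ln pi(H | x) = -1/2 ln|R_n|
                   - (n-1)/2 ln( e'R^{-1}e * x'R^{-1}x - (e'R^{-1}x)^2 )
                   + (n/2 - 1) ln( e'R^{-1}e ),

where R_n is the exact fGn autocorrelation matrix at Hurst exponent H and
e is the vector of ones.  The quadratic forms are computed by the Levinson/
Durbin recursion in O(n^2).  Sampling is plain accept--reject with a
Uniform(0,1) proposal and envelope constant M found by bounded scalar
maximization of the log-posterior; the point estimate is the posterior
median.  One hundred posterior draws suffice for a stable median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from ._toeplitz import hk_log_posterior_many, quad_forms_raw
from .fgn import FGnAcf, validate_series

__all__ = [
    "QuadForms",
    "HKPosterior",
    "toeplitz_forms",
    "hk_log_posterior",
    "sample_hk_posterior",
    "estimate_h_hk",
]

# h is maximized over [H_EPS, 1 - H_EPS]; the posterior is improper at the ends
_H_EPS = 1e-6
# safety margin added to the numerically found maximum of the log-posterior
_LOG_M_MARGIN = 1e-9
# accept-reject gives up after this many proposals
PROPOSAL_BUDGET = 1_000_000
# proposals are drawn and evaluated in fixed-size batches (affects only speed;
# the (h, u) stream, and hence the output, is the same for any batch size
# because whole batches are always drawn)
_BATCH = 256


@dataclass(frozen=True)
class QuadForms:
    """Quadratic forms of the Toeplitz autocorrelation matrix R.

    ``xRx = x'R^{-1}x``, ``eRe = e'R^{-1}e``, ``eRx = e'R^{-1}x`` (e = ones),
    and ``logdetR = ln|R|``.
    """

    xRx: float
    eRe: float
    eRx: float
    logdetR: float


@dataclass(frozen=True)
class HKPosterior:
    """Accept--reject sample of the HK posterior over the Hurst exponent."""

    samples: np.ndarray = field(repr=False)
    point_estimate: float
    log_M: float
    n_proposals: int

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def acceptance_rate(self) -> float:
        return self.n_samples / self.n_proposals


def toeplitz_forms(acf: FGnAcf | np.ndarray, x) -> QuadForms:
    """Quadratic forms of the autocorrelation matrix via the Levinson recursion.

    Parameters
    ----------
    acf : FGnAcf or array-like
        Autocorrelation sequence rho_0..rho_{n-1} defining a positive-definite
        Toeplitz matrix; length must match ``x``.
    x : array-like
        The data vector.

    Raises
    ------
    numpy.linalg.LinAlgError
        If the recursion meets a nonpositive prediction-error variance
        (numerically non-positive-definite R).
    """
    rho = acf.rho if isinstance(acf, FGnAcf) else np.asarray(acf, dtype=float)
    x = np.asarray(x, dtype=float)
    qx, qe, qxe, logdet = quad_forms_raw(rho, x)
    return QuadForms(xRx=qx, eRe=qe, eRx=qxe, logdetR=logdet)


def _check_series_for_hk(x) -> np.ndarray:
    x = validate_series(x)
    if np.var(x) == 0.0:
        raise ValueError("degenerate series: zero sample variance")
    return x


def hk_log_posterior(h: float, x) -> float:
    """Unnormalized log marginal posterior of the Hurst exponent at ``h``.

    Returns -inf when the autocorrelation matrix at ``h`` is numerically
    non-positive-definite.
    """
    h = float(h)
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must lie in (0, 1); got {h}")
    x = _check_series_for_hk(x)
    return float(hk_log_posterior_many(np.array([h]), x)[0])


def _find_log_envelope(x: np.ndarray) -> float:
    """log M: maximized log-posterior over h plus a small safety margin."""
    res = minimize_scalar(
        lambda h: -hk_log_posterior_many(np.array([h]), x)[0],
        bounds=(_H_EPS, 1.0 - _H_EPS),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return -res.fun + _LOG_M_MARGIN


class ProposalBudgetError(RuntimeError):
    """Accept--reject exhausted its proposal budget."""

    def __init__(self, n_accepted, n_samples, log_M, best_rejected):
        self.n_accepted = n_accepted
        self.log_M = log_M
        self.best_rejected = best_rejected
        super().__init__(
            f"accept-reject budget of {PROPOSAL_BUDGET} proposals exhausted with "
            f"{n_accepted}/{n_samples} samples accepted "
            f"(log_M={log_M:.6g}, best rejected log-density={best_rejected:.6g})"
        )


def sample_hk_posterior(x, n_samples: int, seed) -> HKPosterior:
    """Sample the HK posterior of the Hurst exponent by accept--reject.

    Proposals h ~ Uniform(0,1) are accepted when ln u <= ln pi(h|x) - log M,
    u ~ Uniform(0,1), with log M the numerically maximized log-posterior.
    The RNG stream is consumed in batches of h draws followed by u draws;
    accepted values are returned in acceptance order.

    Parameters
    ----------
    x : array-like
        Series of length >= 8 with nonzero variance.
    n_samples : int
        Number of accepted posterior draws required (>= 1).
    seed : int or numpy.random.SeedSequence or numpy.random.Generator
        Identical seeds give identical samples.

    Raises
    ------
    ProposalBudgetError
        If the proposal budget is exhausted before ``n_samples`` acceptances;
        carries ``log_M`` and the best rejected log-density as diagnostics.
    """
    n_samples = int(n_samples)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    x = _check_series_for_hk(x)
    log_M = _find_log_envelope(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    accepted: list[float] = []
    n_proposals = 0
    consumed = 0
    best_rejected = -np.inf
    while len(accepted) < n_samples:
        if consumed >= PROPOSAL_BUDGET:
            raise ProposalBudgetError(len(accepted), n_samples, log_M, best_rejected)
        hs = rng.random(_BATCH)
        us = rng.random(_BATCH)
        lps = hk_log_posterior_many(hs, x)
        ok = np.log(us) <= lps - log_M
        consumed += _BATCH
        for i in range(_BATCH):
            if ok[i]:
                accepted.append(hs[i])
                if len(accepted) == n_samples:
                    n_proposals = consumed - _BATCH + i + 1
                    break
            elif lps[i] > best_rejected:
                best_rejected = lps[i]
    samples = np.array(accepted)
    return HKPosterior(
        samples=samples,
        point_estimate=float(np.median(samples)),
        log_M=log_M,
        n_proposals=n_proposals,
    )


def estimate_h_hk(x, n_samples: int = 100, seed=None) -> float:
    """HK point estimate of the Hurst exponent: median of the posterior sample."""
    return sample_hk_posterior(x, n_samples, seed).point_estimate
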