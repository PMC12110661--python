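"""Contamination models for long-range correlated series.

Six additive contaminant families, each mixed into a base series at an
amplitude A in [0, 1] (t = 1..N is the running index):

    awgn         y = x + A*u,   u iid standard normal
    fgn          y = x + A*p,   p fGn with Hurst exponent Hc (default 0.9)
    short_range  y = x + A*s,   s a fractionally integrated AR(1), standardized
    cyclical     y_t = x_t + A*sin(2*pi*t/tau)        (tau = 365 or 36,500)
    linear       y_t = x_t + sign*A*0.005*t
    quadratic    y_t = x_t + sign*A*0.000005*t^2

The stochastic contaminants (awgn, fgn, short_range) have unit variance so
that A means the same thing across families; the deterministic trends
consume no randomness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .fgn import simulate_fgn, validate_series

__all__ = ["ContaminantSpec", "KINDS", "gen_short_range", "contaminate"]

KINDS = ("awgn", "fgn", "short_range", "cyclical", "linear", "quadratic")

LINEAR_RATE = 0.005  # trend slope per time step at A = 1
QUADRATIC_RATE = 0.000005  # quadratic coefficient at A = 1
SHORT_TAU = 365.0  # short-term cyclical period
LONG_TAU = 36_500.0  # long-term cyclical period
_BURN_IN = 1000  # samples discarded before the short-range segment


def _contaminant_rng(seed) -> np.random.Generator:
    """RNG for contaminant draws, on a stream distinct from the base series.

    Integer seeds are routed through a spawned SeedSequence so that passing
    the same integer to the series simulator and to :func:`contaminate`
    never replays the same Gaussian draws.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return np.random.default_rng(ss.spawn(1)[0])


@dataclass(frozen=True)
class ContaminantSpec:
    """One contaminant family plus its amplitude and family-specific knobs.

    ``tau`` applies to ``cyclical``, ``sign`` to ``linear``/``quadratic``,
    ``Hc`` to ``fgn``, and ``d``/``a1`` to ``short_range``; irrelevant
    parameters are ignored by :func:`contaminate` but still validated.
    """

    kind: str
    A: float
    tau: float = SHORT_TAU
    sign: int = 1
    Hc: float = 0.9
    d: float = 0.25
    a1: float = 0.1

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown contaminant kind {self.kind!r}; choose from {KINDS}")
        if not 0.0 <= self.A <= 1.0:
            raise ValueError(f"amplitude A must lie in [0, 1]; got {self.A}")
        if self.tau <= 0.0:
            raise ValueError(f"cyclical period tau must be positive; got {self.tau}")
        if self.sign not in (1, -1):
            raise ValueError(f"trend sign must be +1 or -1; got {self.sign}")
        if not 0.0 < self.Hc < 1.0:
            raise ValueError(f"contaminant Hurst exponent Hc must lie in (0, 1); got {self.Hc}")
        if not 0.0 <= self.d < 0.5:
            raise ValueError(f"fractional differencing parameter d must lie in [0, 0.5); got {self.d}")
        if abs(self.a1) >= 1.0:
            raise ValueError(f"nonstationary AR parameter: |a1| must be < 1; got {self.a1}")


def _frac_integration_weights(d: float, n: int) -> np.ndarray:
    """MA weights psi_j of (1-B)^{-d}: psi_j = Gamma(j+d) / (Gamma(j+1) Gamma(d)).

    Computed by the stable recursion psi_j = psi_{j-1} * (j - 1 + d) / j.
    """
    psi = np.empty(n)
    psi[0] = 1.0
    for j in range(1, n):
        psi[j] = psi[j - 1] * (j - 1.0 + d) / j
    return psi


def gen_short_range(n: int, d: float = 0.25, a1: float = 0.1, seed=None) -> np.ndarray:
    """Short-range correlated contaminant: fractionally integrated AR(1).

    An AR(1) core w_t = a1*w_{t-1} + u_t (u iid standard normal, autocorrelation
    time constant -1/ln|a1|) is fractionally integrated, s = (1-B)^{-d} w, via
    the truncated binomial moving average.  The first 1000 samples are
    discarded as burn-in and the returned segment is standardized to zero
    sample mean and unit sample variance.
    """
    n = int(n)
    if n < 1:
        raise ValueError(f"length must be positive; got {n}")
    if abs(a1) >= 1.0:
        raise ValueError(f"nonstationary AR parameter: |a1| must be < 1; got {a1}")
    if not 0.0 <= d < 0.5:
        raise ValueError(f"fractional differencing parameter d must lie in [0, 0.5); got {d}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = n + _BURN_IN
    u = rng.standard_normal(m)
    w = lfilter([1.0], [1.0, -a1], u)
    s = lfilter(_frac_integration_weights(d, m), [1.0], w)
    s = s[_BURN_IN:]
    sd = s.std()
    if sd == 0.0:  # cannot happen for Gaussian input; guard division anyway
        raise FloatingPointError("degenerate short-range contaminant")
    return (s - s.mean()) / sd


def contaminate(x, spec: ContaminantSpec, seed=None) -> np.ndarray:
    """Add the contaminant described by ``spec`` to the series ``x``.

    The deterministic trend kinds (cyclical, linear, quadratic) ignore
    ``seed`` and consume no randomness; for stochastic kinds the seed stream
    must be independent of the one that generated ``x``.
    """
    x = validate_series(x)
    n = len(x)
    kind, A = spec.kind, spec.A
    if kind == "awgn":
        return x + A * _contaminant_rng(seed).standard_normal(n)
    if kind == "fgn":
        return x + A * simulate_fgn(spec.Hc, n, _contaminant_rng(seed))
    if kind == "short_range":
        return x + A * gen_short_range(n, spec.d, spec.a1, _contaminant_rng(seed))
    t = np.arange(1.0, n + 1.0)
    if kind == "cyclical":
        return x + A * np.sin(2.0 * np.pi * t / spec.tau)
    if kind == "linear":
        return x + spec.sign * A * LINEAR_RATE * t
    if kind == "quadratic":
        return x + spec.sign * A * QUADRATIC_RATE * t**2
    raise ValueError(f"unknown contaminant kind {kind!r}")  # unreachable
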