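# Methods

## Model

All estimators in `hurstkit` target the Hurst exponent H of a stationary
long-range correlated Gaussian process. The reference model is fractional
Gaussian noise (fGn): zero mean, unit variance, and exact lag-k
autocorrelation

    rho_k = (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H}) / 2,    0 < H < 1.

The exact finite-lag form is used throughout, never the asymptotic power law
H(2H-1)k^{2H-2}: at the short lengths this package is built for (N = 32–1024)
the two differ materially at small lags.

## fGn simulation

`simulate_fgn` uses Davies–Harte circulant embedding: the n×n Toeplitz
covariance is embedded in a circulant of size m = 2(n−1), whose eigenvalues
are the real FFT of the first row. Complex Gaussian coefficients scaled by
sqrt(lam_k) and inverse-transformed give a sample whose first n entries have
*exactly* the fGn autocovariance — no approximation, no empirical
rescaling. Output variance is the theoretical 1; consequently the
*sample* variance of a single series falls short of 1 by about n^{2H−2}
(the variance of the sample mean), e.g. E[sample var] ≈ 0.89 at H = 0.8,
N = 256. That is a property of every exact simulator, not a defect, and it
is why the test suite checks second moments about the known zero mean.

Numerical choices: embedding size 2(n−1) (the classical construction); a
negative eigenvalue raises an error naming (H, n) rather than clipping —
across the whole study grid H ∈ {0.1,…,0.9} × N ∈ {32,…,1024} the spectrum
is verifiably nonnegative, so the error path never triggers there. The RNG
stream is consumed in a fixed order (m standard normals laid out by
frequency, real before imaginary), so a seed fully determines the series
across platforms.

## The Bayesian HK estimator

The HK method samples H from the marginal posterior implied by the fGn
likelihood with noninformative location/scale priors integrated out:

    ln pi(H|x) = -1/2 ln|R_n|
                 - (n-1)/2 ln( e'R⁻¹e · x'R⁻¹x - (e'R⁻¹x)² )
                 + (n/2 - 1) ln( e'R⁻¹e )   + const,

R_n the exact fGn autocorrelation matrix at H, e the ones vector. The
bracket is nonnegative by Cauchy–Schwarz in the R⁻¹ inner product, and the
whole expression is invariant under affine transforms of the data (shift
exactly, scale up to an H-free constant) — both properties are tested.
Location and scale are never sampled; only H is.

The four quadratic forms come from one Levinson/Durbin pass in O(n²) time
and O(n) memory: the recursion yields order-t prediction coefficients and
error variances v_t, giving ln|R| = Σ ln v_t and the forms via the
innovations factorization. A nonpositive v_t signals numerical
non-positive-definiteness; the log-posterior returns −∞ there, which the
accept–reject sampler simply rejects. The kernel is numba-compiled (a pure
NumPy/Python fallback with the identical algorithm runs when numba is
absent); correctness is pinned to dense Cholesky oracles at n ≤ 64 to
relative error 1e−8.

Sampling is plain accept–reject: proposals h ~ Uniform(0,1), accepted when
ln u ≤ ln pi(h|x) − ln M. ln M is found by bounded scalar maximization of
the log-posterior on [1e−6, 1−1e−6] (absolute tolerance 1e−6 in h) plus a
1e−9 safety margin so the acceptance test can never exceed the numerical
maximum. Proposals are drawn in fixed batches of 256 (h draws then u draws),
which affects speed only — the (h, u) stream is identical for any batch
size. A budget of 10⁶ proposals per series raises an error carrying ln M
and the best rejected log-density; silent truncation never happens. The
point estimate is the median of 100 accepted draws (the even-count median is
the midpoint of the central order statistics); 100 draws is the default
because the median is already stable there and cost scales linearly.

## DFA

First- and second-order DFA follow the standard pipeline: profile
y_i = Σ_{k≤i}(x_k − mean(x)); for each bin size s, floor(n/s)
non-overlapping windows taken from the start (the trailing remainder is
discarded; no reversed second pass); per-window least-squares polynomial of
degree 1 or 2 on the centered within-window index (centering changes
nothing mathematically, only conditioning); f(s) is the square root of the
grand mean of squared residuals (mean over windows of the per-window mean,
which coincides with the overall mean for equal windows). Ĥ is the OLS
slope of ln f on ln s — the log base is irrelevant to a slope.

Default bin sizes are the arithmetic sequence 4, 8, 12, … up to N/2, the
conventional [4, N/2] fitting range; a `scales` override exists because the
fitting range genuinely matters (see Limitations). Zero fluctuation at any
scale (e.g. an exactly polynomial input) is an error rather than a silent
−∞ in the log fit.

## Contamination models

Six additive families, each at amplitude A ∈ [0, 1], index t = 1..N:

| kind         | added term                        | parameters (default)      |
|--------------|-----------------------------------|---------------------------|
| awgn         | A·u_t, u iid N(0,1)               | —                         |
| fgn          | A·p_t, p fGn(Hc)                  | Hc = 0.9                  |
| short_range  | A·s_t, standardized ARFIMA(1,d,0) | d = 0.25, a1 = 0.1        |
| cyclical     | A·sin(2πt/τ)                      | τ = 365 or 36,500         |
| linear       | ±A·0.005·t                        | sign ∈ {+1, −1}           |
| quadratic    | ±A·0.000005·t²                    | sign ∈ {+1, −1}           |

The short-range contaminant is an AR(1) core w_t = a1·w_{t−1} + u_t
fractionally integrated by (1−B)^{−d} through the truncated binomial moving
average ψ_j = Γ(j+d)/(Γ(j+1)Γ(d)) (computed by the stable recursion
ψ_j = ψ_{j−1}(j−1+d)/j), with a 1000-sample burn-in discarded. Its
population variance is not 1, so the returned segment is empirically
standardized; awgn and fgn rely on their theoretical unit variance. This
keeps the meaning of A comparable across families. The structural reading
of the short-range recipe (AR core first, fractional integration outside)
is a documented modeling choice; the d = 0 limit collapses to a pure AR(1)
with lag-1 autocorrelation a1, which is tested, and the d = 0.25 case is
checked against the ARFIMA MA(∞) autocorrelation computed independently.

The cyclical term is evaluated over the running index t (a fixed phase
would be a constant offset, not a trend). Trend indexing is 1-based.
Deterministic kinds consume no randomness; stochastic kinds draw from a
stream spawned off the given seed, so reusing one integer seed for both the
base series and the contaminant can never replay identical Gaussians.

## Monte Carlo harness

`run_cell` simulates n_reps fGn series for one (estimator, H, N,
contaminant, A) cell, contaminates, estimates, and summarizes: mean, SD,
and a 95% CI of the mean (normal approximation mean ± 1.96·SD/√n_reps by
default; percentile CI of the replicate estimates as an option). Replicates
whose estimator raises are excluded and counted in n_failures; a cell with
more than 10% failures is marked failed (NaN summaries). Estimator HK uses
100 posterior draws; DFA1/DFA2 use the default scale set.

Substream seeding makes the entire grid a pure function of (config, master
seed): each replicate derives integer seeds from a blake2b hash of a
canonical key string (reduced mod 2³¹). The fGn stream is keyed by
(master_seed, H, N, replicate) — deliberately *excluding* estimator,
contaminant kind, and amplitude — so all estimators see identical inputs,
A = 0 cells of every kind coincide exactly with the uncontaminated cell,
and contaminant families are compared with common random numbers. The
contaminant stream adds the full contaminant identity; the estimator stream
adds the estimator name.

`run_grid` iterates kinds × H × N × A × estimators, appends each completed
row to the results CSV, and on restart skips rows already present —
interrupted study-scale runs resume. The default n_reps is 200; the full
study scale (1000 replicates, 9 H × 6 N × 11 A × 9 contaminant conditions
× 3 estimators) is a config change, not a code change.

`decision_map` reduces the results to a per-cell verdict: the estimator
minimizing |mean Ĥ − H|, provided that minimum is ≤ 0.1 (configurable);
ties break in the fixed preference order HK > DFA1 > DFA2, and `none`
marks cells where no estimator qualifies.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions exactly: exact fGn at the
stated H and N grids, unit-variance stochastic contaminants, the printed
trend coefficients. Passing tests therefore demonstrate estimator behavior
*under the fGn-plus-additive-contaminant model*. Real behavioral series
deviate from that model in ways the generator deliberately does not
emulate: non-Gaussian marginals, multiplicative or state-dependent noise,
missing samples and outliers, nonstationary variance, and multifractality.
Conclusions about which estimator to trust transfer only to the extent the
contaminant families span what corrupts a given empirical record.

## Numerical scale choices

Monte Carlo checks in the test suite use 200–1000 replicates depending on
the variance of the quantity under test, and the bundled demo grid uses
tens of replicates per cell; these sizes put Monte Carlo error well inside
the asserted tolerances while keeping the default suite desk-scale. The
acceptance script uses 200 replicates per H for the short-series bias (its
Monte Carlo SE is ≈ 0.004 per H) and 1000 for the trend blow-up mean
(SE ≈ 0.0006).

## Known limitations

- **DFA fitting range.** The slope depends on the scale set. With the
  default arithmetic scales up to N/2, the mean DFA1 estimate for H = 0.2,
  N = 512 under a full-amplitude linear trend is ≈ 0.93: the crossover
  between the noise regime (f ~ s^0.2) and the trend regime (f ~ s²) sits
  near the top of the available scales, so the fitted slope blends the two.
  Published DFA implementations with other (often unstated) scale sets
  report values above 1 in this regime; with log₂-spaced scales ours gives
  ≈ 0.69. This sensitivity is exactly why the scale override exists, and
  why single-number DFA comparisons across packages need the scale set
  pinned.
- The HK estimator assumes the fGn correlation family; under gross model
  misspecification its posterior is still well-defined but its median
  estimates the best-fitting fGn, not "the" H.
- H ≥ 1 regimes (nonstationary, fBm-like signals) are out of scope; the
  posterior domain and the simulator are restricted to H ∈ (0, 1).
- The accept–reject sampler's cost grows as the posterior sharpens
  (acceptance rate ~ posterior width); at N = 1024 expect ~2000 proposals
  for 100 draws, i.e. under a second per series on one CPU.
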