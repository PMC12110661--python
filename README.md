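# hurstkit

Hurst exponent estimation for **short, contaminated time series**, built for
behavioral and physiological data where a few hundred samples is a luxury:
self-report mood series, stride intervals, reaction times, heart-rate records.

The Hurst exponent H ∈ (0, 1) quantifies long-range temporal correlation:
H < 0.5 anti-persistent, H = 0.5 uncorrelated, H > 0.5 persistent. `hurstkit`
provides

- an **exact fractional Gaussian noise (fGn) simulator** via Davies–Harte
  circulant embedding, with the exact autocorrelation
  ρₖ = (|k+1|²ᴴ − 2|k|²ᴴ + |k−1|²ᴴ)/2;
- the **Bayesian Hurst–Kolmogorov (HK) estimator**: accept–reject samples of H
  from its marginal posterior under the fGn likelihood,
  ln π(H|x) ∝ −½ ln|Rₙ| − ((n−1)/2) ln(e'R⁻¹e·x'R⁻¹x − (e'R⁻¹x)²)
  + (n/2 − 1) ln(e'R⁻¹e), with the Toeplitz quadratic forms computed by a
  Levinson/Durbin recursion in O(n²); the point estimate is the posterior
  median of 100 draws;
- **first- and second-order DFA** (detrended fluctuation analysis): the slope
  of ln f(s) on ln s, where f(s) is the RMS residual of polynomially
  detrended profile windows over bin sizes 4, 8, 12, …, N/2;
- **six contamination models** — additive white Gaussian noise, fGn (H = 0.9),
  short-range correlations (a fractionally integrated AR(1)), cyclical trends
  (τ = 365 or 36,500), and linear (±0.005·t) and quadratic (±0.000005·t²)
  trends — each mixed in at amplitude A ∈ [0, 1];
- a **Monte Carlo harness** that sweeps (H, N, A, contaminant, estimator)
  grids and emits a per-cell **decision map**: which estimator achieves
  |mean Ĥ − H| ≤ 0.1, if any.

## Worked example

```python
from hurstkit import simulate_fgn, sample_hk_posterior, estimate_h_dfa

x = simulate_fgn(0.8, 256, seed=42)          # exact fGn, H = 0.8, N = 256
post = sample_hk_posterior(x, 100, seed=1)   # Bayesian HK posterior sample
print(post.point_estimate)                   # 0.720
print(estimate_h_dfa(x, order=1).h_hat)      # 0.735
print(estimate_h_dfa(x, order=2).h_hat)      # 0.701
```

All three estimates sit near the true H = 0.8; for a single 256-sample series
deviations of this size are expected replicate noise (the HK posterior SD at
this length is about 0.04–0.05). Running
`python examples/contamination_bias.py` shows the characteristic bias under
contamination — the mean HK estimate at H = 0.9, N = 256 slides from 0.893 at
A = 0 to 0.668 at A = 1 of added white noise, toward the contaminant's own
H = 0.5.

The `examples/` scripts each exercise one capability end to end;
`examples/demo_grid.yaml` is a minute-scale benchmarking grid and
`examples/paper_grid.yaml` the full study-scale one (cluster-scale; the
harness resumes from a partial results CSV).

## Command line

```sh
hurstkit simulate -H 0.7 -n 128 --seed 42 --out x.txt
hurstkit contaminate x.txt --kind linear -A 1.0 --out y.txt
hurstkit estimate y.txt --method hk --seed 1
hurstkit experiment --config examples/demo_grid.yaml --out results.csv
hurstkit decision-map results.csv --out decisions.csv
```

Series files are plain text, one value per line (single-column CSV with a
header also works). Config files are flat YAML; axes accept lists or
comma-separated strings, and contaminant kinds take optional parameters as
`cyclical:365`, `linear:+`, `quadratic:-`. Results CSV columns: estimator,
contaminant, H_true, N, A, tau, sign, n_reps, n_failures, mean_hhat, sd_hhat,
ci_low, ci_high.

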