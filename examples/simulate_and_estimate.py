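"""Simulate fractional Gaussian noise and estimate its Hurst exponent.

Generates one persistent series (H = 0.8, N = 256), then estimates H with
the Bayesian HK method and with first- and second-order DFA.  The HK
estimate is the median of 100 posterior draws; the DFA estimates are
log-log slopes of the fluctuation function over bin sizes 4, 8, ..., N/2.
"""

from hurstkit import estimate_h_dfa, sample_hk_posterior, simulate_fgn

H_TRUE, N = 0.8, 256

x = simulate_fgn(H_TRUE, N, seed=42)
print(f"simulated fGn: H = {H_TRUE}, N = {N}, sample mean {x.mean():+.3f}, sample sd {x.std():.3f}")

post = sample_hk_posterior(x, n_samples=100, seed=1)
print(f"HK estimate:   {post.point_estimate:.3f}  "
      f"(acceptance rate {post.acceptance_rate:.2f}, {post.n_proposals} proposals)")

for order in (1, 2):
    est = estimate_h_dfa(x, order=order)
    print(f"DFA{order} estimate: {est.h_hat:.3f}  ({len(est.scales)} scales, 4..{est.scales[-1]})")

print("\nAll three should sit near the true H = 0.8; on a single short series the")
print("HK estimate is typically the closest and the least dispersed.")
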