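"""Run a small benchmarking grid and derive the which-method-to-use map.

Sweeps two Hurst exponents, two series lengths, and two awGn amplitudes
with all three estimators (20 replicates per cell), then reports per cell
which estimator lands within 0.1 of the true H with the smallest error.
"""

from hurstkit import decision_map, run_grid

config = dict(
    H=[0.3, 0.8],
    N=[64, 256],
    A=[0.0, 1.0],
    kinds=["awgn"],
    estimators=["HK", "DFA1", "DFA2"],
    n_reps=20,
    master_seed=7,
)

table = run_grid(config)
print("grid summaries (one row per estimator x cell):")
print(table[["estimator", "H_true", "N", "A", "mean_hhat", "sd_hhat"]].to_string(index=False))

verdicts = decision_map(table, threshold=0.1)
print("\ndecision map (|mean - H| <= 0.1; ties prefer HK, then DFA1):")
print(verdicts[["H_true", "N", "A", "best", "min_abs_error"]].to_string(index=False))

print("\n'none' marks cells where no estimator is accurate enough —")
print("typical for heavily contaminated anti-persistent series.")
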