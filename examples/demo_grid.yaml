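# Desk-scale demo grid: runs in about a minute.
H: 0.3, 0.6, 0.9
N: 32, 64
A: 0.0, 0.5, 1.0
kinds: awgn, linear:+
estimators: HK, DFA1, DFA2
n_reps: 20
master_seed: 1
out: demo_results.csv
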