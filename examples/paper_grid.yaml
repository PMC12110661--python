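# Full study-scale grid: 9 H x 6 N x 11 A x 9 contaminant conditions x
# 3 estimators at 1000 replicates per cell.  This is a cluster-scale run;
# the harness accepts it and resumes from a partial results CSV.
H: 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9
N: 32, 64, 128, 256, 512, 1024
A: 0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0
kinds: awgn, fgn, short_range, cyclical:365, cyclical:36500, linear:+, linear:-, quadratic:+, quadratic:-
estimators: HK, DFA1, DFA2
n_reps: 1000
master_seed: 1
out: paper_results.csv
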