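# Single long agent-based run at small mutation rate with a thinned
# trajectory (cooperator count, mean capacitor volume per strategy,
# number of occupied subpopulations) streamed to TSV.
experiment: abm
params: {N: 40, r: 3.2, g: 5, beta: 0.1, theta: 0.12, M: 50, mu: 5.0e-5}
seeds: [1]
n_steps: 11000000
burn_in: 1000000
thin: 10000
out_dir: results/abm_trajectory
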