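# Agent-based Moran runs across mutation rates; time-averaged cooperator
# fraction per (mu, seed) after burn-in.
experiment: abm
params: {N: 40, r: 3.2, g: 5, beta: 0.1, theta: 0.12, M: 50, chi_slope: 0.1}
mu_values: [0.5, 0.05, 0.01]
seeds: [1, 2, 3]
n_steps: 11000000
burn_in: 1000000
out_dir: results/abm_mutation
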