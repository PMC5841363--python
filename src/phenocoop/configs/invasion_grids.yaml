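# Pairwise invasion-rate grids: rate of a single mutant strain (row strategy
# C/D, volume K_mutant) taking over a monomorphic resident population.
experiment: invasion_grid
params: {N: 40, r: 3.2, g: 5, beta: 0.1, theta: 0.12, M: 50, chi_slope: 0.1}
out_dir: results/invasion_grids
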