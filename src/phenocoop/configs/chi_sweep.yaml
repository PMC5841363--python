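# Stationary distributions under different interaction-to-selection time
# scales chi(x) = slope * x, at fixed capacitor cost rate.
experiment: stationary
params: {N: 40, r: 3.2, g: 5, beta: 0.1, theta: 0.12, M: 50}
chi_slopes: [0.01, 0.5, 2, 5]
out_dir: results/chi_sweep
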