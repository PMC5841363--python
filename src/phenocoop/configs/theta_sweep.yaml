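# Stationary distribution of the embedded strain chain across capacitor
# cost rates theta; reports the overall cooperation level per sweep point.
experiment: stationary
params: {N: 40, r: 3.2, g: 5, beta: 0.1, M: 50, chi_slope: 0.1}
theta_values: [0, 0.05, 0.12, 0.3, 0.5, 1]
out_dir: results/theta_sweep
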