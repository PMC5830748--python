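# frozen smoke-run configuration: synthetic contaminated-sediment
# experiment, reduced bootstrap/posterior sizes
experiment: 1
simulate: true
seed: 42
bootstrap_reps: 200
posterior_draws: 1000
out_dir: isoniche_out
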