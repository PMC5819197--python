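# Packaged demo profile: desk-scale cohort, fixed seed.
model: reference
n_simulations: 5000
master_seed: 20180220
sampling: uniform
screen_days: [7, 14, 21, 40]
evaluation_days: [14, 21]
markers: [I10, T1, FN]
n_bins: 50
cv_folds: 10
horizon: 40
save_trajectories: false
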