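# Desk-scale pipeline profile for `ibdsig run --config examples/desk_config.yaml`.
# Full-cohort defaults are q=1, p_chains=100, the 23-algorithm registry
# ("all"); this profile shrinks the search so both tasks finish in minutes.
task: both
q: 10
p_chains: 10
cv_folds: 10
registry: null          # null = 5-spec desk registry; "all" = the full 23
min_size: 5
ann_layers: [1, 2, 5, 10]
lasso: true
split_fraction: 0.8
seed: 0
out_dir: scratch/desk_run
simulation:
  n_samples: 300
  n_genes: 500
  n_informative: 24
  effect_size: 2.0
  uc_cd_effect_size: 0.8
  informative_task: both
  seed: 0
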