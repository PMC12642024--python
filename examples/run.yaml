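# Full pipeline run on a simulated cohort.
simulation:
  n_hsa: 90
  n_lsa: 37
  b_int: 1.2
  na_missing_rate: 0.04
  seed: 1
min_trials: 30
happy_floor: 0.75
angry_ceiling: 0.25
cov_type: HC3
alpha: 0.05
seed: 1
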