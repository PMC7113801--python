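# Desk-scale demonstration run: a small drift cohort, short windows,
# 50 training epochs. Finishes in about a minute on one core.
cohort:
  n_event: 12
  n_censored: 60
  horizon_steps: 16
  min_outcome_hours: 17
  max_stay_hours: 120
prep:
  horizon_steps: 16
model:
  epochs: 50
  batch_size: 128
  learning_rate: 0.003
  dtype: float32
eval:
  horizons: [1, 4, 8, 12, 16]
seed: 7
out_dir: demo_run
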