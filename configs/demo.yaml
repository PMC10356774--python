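# 2,000-patient demonstration pipeline (runs end-to-end in a few minutes on one CPU)
seed: 7
out_dir: scratch/demo_run
simulate:
  n_patients: 2000
  risk_effect: 2.0
  # elevated outcome rate so the small demo test split contains cases
  outcome_prevalence_target: 0.05
build_cohort:
  index_year: 2018
  min_visits: 3
  min_count: 1
model:
  d_model: 32
  n_layers: 1
  n_heads: 4
  d_ff: 64
  max_len: 64
pretrain:
  n_steps: 150
  batch_size: 32
  lr: 0.003
finetune:
  n_steps: 200
  batch_size: 32
  lr: 0.003
  eval_every: 50
  patience: 3
evaluate:
  n_resamples: 500
  k_percent: 5.0
attribute:
  n_trajectories: 20
  n_steps: 8
export_viz:
  min_occurrences: 20
  min_code_count: 5
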