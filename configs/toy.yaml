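# Toy-scale end-to-end configuration: 40 participants, 20 regions, 32/32 hidden.
# Sized to run the full phase chain on one CPU well inside 15 minutes.
seed: 7
out: runs/toy
tasks: [emotional_faces, stroop]
cohort:
  n_participants: 40
  n_regions: 20
  ef_duration_s: 197.6
  stroop_duration_s: 197.6
  press_steps: 3
model:
  n_hidden_hyper: 32
  n_hidden_main: 32
  n_bold: 20
  dropout: 0.0
  action_bias_logit: -4.8  # start action biases at the press base rate
train:
  segment_len: 262
  batch_size: 50
  lr: 0.003            # toy-scale; the full-scale default is 1e-6
  max_epochs: 700
  early_stop_patience: 700
  val_fraction: 0.1
  restore_best: false
loss:
  lambda_action: 10.0  # toy-scale; the full-scale default is 1.0
  lambda_bold: 1.0
glm:
  dct_cutoff_hz: 0.01
pls:
  threshold: 0.5
intervention:
  smoothgrad_samples: 100
  smoothgrad_noise: 0.1
  sd_threshold: 2.5
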