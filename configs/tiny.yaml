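# Desk-scale defaults: a 2-layer, 4-head, 64-dim encoder trained on the
# synthetic kinome. Finishes end-to-end in minutes on one CPU.
model:
  n_layers: 2
  n_heads: 4
  embed_dim: 64
  ffn_dim: 128
  max_len: 256

synth:
  kinases_per_family: 4
  domain_length: 80
  full_length: 120
  consensus_mutation_rate: 0.05
  n_substrates: 200
  substrate_length: 300
  seed: 0

pretrain:
  learning_rate: 1.0e-3
  epochs: 6
  batch_size: 64
  mlm_rate: 0.15

finetune:
  learning_rate: 1.5e-3
  gamma: 2.0
  batch_size: 64
  # adaptive schedule: hold the peak rate until validation focal loss
  # clears breakout_val, then decay over decay_epochs
  breakout_val: 0.15
  hold_min_epochs: 9
  hold_max_epochs: 17
  decay_epochs: 8
  epochs: 25
  patience: 99

augment:
  resample_target_large: 1118
  resample_target_small: 50
  resample_threshold: 50
  max_shift: 5
  kinase_mask_rate: 0.05
  enable_resample: false
  enable_shift: true
  enable_mask: true
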