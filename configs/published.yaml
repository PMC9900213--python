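# Published-scale configuration: 6 attention layers of 12 heads producing
# 768-dim embeddings, MLM pre-training at lr 5e-5, focal fine-tuning at
# lr 2e-5 with gamma 2, early-stopping patience 5, and a 1:16
# positive:negative training ratio (n=15 easy + m=1 hard). Training at
# this scale requires GPU-class compute and a large curated corpus; the
# configuration is provided for completeness and for loading published
# hyperparameters, not for CPU use.
model:
  n_layers: 6
  n_heads: 12
  embed_dim: 768
  ffn_dim: 3072
  max_len: 512

pretrain:
  learning_rate: 5.0e-5
  epochs: 50
  batch_size: 48
  mlm_rate: 0.15

finetune:
  learning_rate: 2.0e-5
  gamma: 2.0
  batch_size: 48
  epochs: 50
  patience: 5
  n_easy: 15
  m_hard: 1

augment:
  resample_target_large: 1118
  resample_target_small: 50
  resample_threshold: 50
  max_shift: 5
  kinase_mask_rate: 0.05
  enable_resample: true
  enable_shift: true
  enable_mask: true
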