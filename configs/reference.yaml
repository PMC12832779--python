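# Reference-scale training configuration: 128^3 ROI-centered patches,
# patch-16 embedding to an (8,8,8) x 384 token grid, batch 4, initial
# learning rate 2e-5 with cosine decay. Too large to train on CPU; see
# configs/scaled.yaml for the desk-scale configuration.
learning_rate: 2.0e-5
batch_size: 4
epochs: 100
seed: 0
optimizer: ranger
schedule: cosine
train_fraction: 0.8
val_fraction: 0.15
augment:
  rotate: true
  flip: true
  noise: true
  intensity: true
  shift: true
loss:
  alpha: 1.0        # overwritten per task with the training-split class ratio
  gamma: 2.0
  beta: 1.0
  epsilon: 1.0e-7
  form: as_printed
encoder:
  in_channels: 5
  input_size: 128
  patch_size: 16
  embed_dim: 384
  n_blocks: 12
  n_heads: 6
  adapter_reduction: 8
  tabular_dim: 101
  mlp_ratio: 4
  freeze_backbone: true
mfeb_width: 8
mfeb_dropout: 0.1
bypass_mfeb: false
use_adapters: true
tasks: both
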