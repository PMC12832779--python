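# Desk-scale configuration that trains on one CPU in minutes:
# 32^3 patches, embed 48, 2 transformer blocks.
learning_rate: 1.0e-3
batch_size: 4
epochs: 14
seed: 0
optimizer: ranger
schedule: cosine
augment:
  rotate: false
  flip: true
  noise: true
  intensity: true
  shift: false
encoder:
  in_channels: 5
  input_size: 32
  patch_size: 4
  embed_dim: 48
  n_blocks: 2
  n_heads: 6
mfeb_width: 4
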