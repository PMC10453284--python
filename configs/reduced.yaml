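# Reduced-width configuration for CPU-scale experiments on synthetic data.
learning_rate: 0.001
optimizer: adam
epochs: 30
steps_per_epoch: 10
batch_size: 4
patch_size: 64
noise_sd_max: 0.02
rotation_mode: right-angle
val_fraction: 0.2
seed: 0
reduction: mean
aux_mae_supervision: false
model:
  base_width: 8
  depth: 3
  n_subsets: 4
  cot_groups: 4
  key_kernel: 3
  attn_kernel: 3
  fuse_hidden: 8
  fuse_mode: concat
  mve_style: res2net
  mae_style: cot
  mae_decoder_attention: false
  use_mfi: true
  seed: 0
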