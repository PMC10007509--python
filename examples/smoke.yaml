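# Desk-scale smoke experiment: completes in a few CPU-minutes.
#   usanomaly run --config examples/smoke.yaml --out scratch/smoke
image:
  height: 64
  width: 64
  channels: 1
counts:
  train: 60
  val: 16
  test: 16
lesion:
  area_min_px: 50
  area_max_px: 400
  drop_min: 0.4
  drop_max: 0.7
  softness: 1.0
speckle:
  scale: 0.3
  smoothness: 8.0
model:
  kinds: [ae, vae, swae]
  latent_dim: 128
  channels: [16, 32, 64, 64]
train:
  batch_size: 16
  epochs: 10
  lr_max: 0.0002
evaluation:
  thresholds: [0.1, 0.2, 0.3]
  use_algorithm1: true
  size_bins: 5
seed: 1
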