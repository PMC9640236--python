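# slim desk-scale configuration: 64-px phantoms, 1/8-width network
data:
  dir: phantoms
preprocess:
  target_side: 64
  k: 5
  seed: 0
model:
  input_side: 64
  num_classes: 3
  width_multiplier: 0.125
train:
  learning_rate: 2.0e-3
  batch_size: 8
  max_epochs: 25
  early_stop_patience: 10
  seed: 0
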