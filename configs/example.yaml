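# Desk-scale pipeline: synthetic 3-plate screen, tiny-cnn trained from scratch.
seed: 1

data:
  viability_lower: 0.3
  viability_upper: 0.8
  crop_size: 128

synth:
  n_plates: 3
  n_dmso_wells_per_plate: 4
  fields_per_well: 9
  image_size: [256, 256]

augment:
  crop_size: 128
  noise_sd: 0.01

model:
  backbone: {name: tiny-cnn, feature_dim: 64}
  head:
    embedder_widths: [512, 128]
    classifier_widths: [64]
    n_classes: 3

loss: {tau: 0.1, lambda1: 0.5, lambda2: 0.5}

sampler: {n_plates: 2, n_samples: 5, n_classes: 3}

train:
  learning_rate: 0.001   # from-scratch rate for tiny-cnn; use 1.25e-5 when fine-tuning
  epochs: 120

eval: {k: 1}
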