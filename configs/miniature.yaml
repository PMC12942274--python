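# Desk-scale study preset: 200 low-contrast scenes, two-phase training.
scene:
  seed: 2025
n_samples: 200
test_fraction: 0.2
val_fraction: 0.1
split_seed: 2025
run:
  phase2_lr: 0.002
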