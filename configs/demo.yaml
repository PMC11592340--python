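# Bundled demo configuration: full comparison pipeline at desk scale.
seed: 1
generator:
  n_subjects: 4
  n_steps: 10
  noise_sd: 0.02
trainer:
  train: true
  total_timesteps: 2048
  update_interval: 512
  minibatch_size: 128
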