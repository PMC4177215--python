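# Desk-scale simulation run: all three models on a coupled two-region dataset.
mode: combined
seed: 0
simulation:
  n_train: 200
  n_test: 30
  image_size: 128
  image_kind: pink_noise
  frequencies: [1, 2, 4]
  n_erc: 20
  n_loc: 30
  erc_snr: 2.0
  loc_snr: 1.0
  test_repeats: 13
  kernel_sparsity: 0.01
  latent_shares: {V1: 0.2, V2: 0.45, V3: 0.7}
  low_freq_bias: 2.0
  mixing_density: 0.2
train:
  learning_rate: 1.0e-4
  max_iters: 5000
  n_bootstrap: 10
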