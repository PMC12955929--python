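# Desk-scale run configuration for the CLI commands.
# Unknown keys are rejected; every value shown is also the section default
# unless noted.
model:
  d_model: 32            # library default is 128; 32 trains in seconds
  n_heads: 4
  n_layers: 1            # spectral attention blocks per view
  k: 2                   # Laplacian hop order in the attention modulation
  transformer_layers: 1
  message_rule: modulated_div   # or sum_div / scaled_lk
  laplacian: normalized         # or combinatorial
objectives:
  gamma: 0.1             # dynamic task weighting magnitude
  tau: 0.1               # contrastive temperature
  lambda_contrastive: 0.1
  beta_cb: 0.99          # class-balance hyperparameter
training:
  epochs: 50
  batch_size: 16
  lr: 3.0e-3
io:
  table: fixtures        # or a path to a delimited SMILES table
  n_fixture_molecules: 32
  fixture_noise_sd: 0.0
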