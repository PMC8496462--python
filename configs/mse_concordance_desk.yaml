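# Deviation vs reference fold-change MSE over random-set normalizations.
experiment: mse_concordance
n_random_sets: 100
seed: 0
sim:
  n_genes: 4000
  n_samples: [15, 15]
  mode: heterogeneous
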