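# Deviation of reference-subset scalings vs random-gene-set scalings.
experiment: random_reference_null
n_replicates: 5
n_draws: 50
seed: 0
sim:
  n_genes: 10000
  n_samples: [20, 20]
  de_fraction: 0.5
  mode: heterogeneous
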