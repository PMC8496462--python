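# Desk-scale contamination sweep: deviation and DE metrics as the scaling
# set mixes in a growing fraction of differential genes.
experiment: contamination_sweep
n_replicates: 5
seed: 0
sim:
  n_genes: 10000
  n_samples: [20, 20]
  de_fraction: 0.5
  mode: heterogeneous
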