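# Desk-scale normalizer comparison across DE fractions 0.1..0.9.
experiment: normalizer_comparison
n_replicates: 5
seed: 0
sim:
  n_genes: 10000
  n_samples: [20, 20]
  mode: heterogeneous
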