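# Full-scale normalizer comparison (largest simulated gene count); not
# exercised by the test suite.
experiment: normalizer_comparison
n_replicates: 10
seed: 0
sim:
  n_genes: 50000
  n_samples: [20, 20]
  mode: heterogeneous
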