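# Small self-contained demo: simulate a 4-tumor cohort and run every stage.
seed: 7
simulate:
  enabled: true
  n_groups: 4
  cells_per_group: 25
  n_lnc: 400
  n_coding: 200
  n_modules: 3
  module_size: 25
  stemness_set_size: 20
  subtype_set_sizes: [6, 6, 6, 6]
  n_multivariant_genes: 8
  variants_per_gene: 12
  top_frac: 0.25
structure:
  top_n: 150
  top_k_abundant: 30
som:
  train_n: 150
  epochs: 60
signatures:
  n_random: 100
  q: 0.01
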