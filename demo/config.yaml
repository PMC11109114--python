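seed: 11
dose_sim:
  event_counts: [1, 4, 20, 100]
  n_cells: 20000
  n_replicates: 3
sc_sim:
  n_genes: 2000
  n_cells_per_group: 300
  class_counts: {A: 100, B: 100, D: 50, E: 20, AD: 50}
screening:
  top_n_multifiltered: 50
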