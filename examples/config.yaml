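# Demonstration pipeline configuration: a synthetic cohort of 120 tumours
# with 8 embedded horizontal-transfer events, analysed end to end.
seed: 11
stages: [simulate, assign, detect, enrich, date, copy_number, phase, expression]

simulate:
  n_tumours: 120
  n_ht_events: 8
  event_ages: [469.28, 469.28, 100.0, 50.0, 29.4, 29.4, 29.4, 10.0]

enrich:
  target_haplotype: A1d1a
  replicates: 10000
  seed: 76

rate_anchor:
  mean_mutations: 9.437
  divergence_years: 469.28
  divergence_interval: [240.34, 744.31]

copy_number:
  mean_mt_depth: 600
  mean_nuc_depth: 100
  tumour_fraction: 0.8

expression:
  group_sizes: {A1d1a: 15, CTVT_HT: 15}
  affected_group: A1d1a
  effect_fraction: 0.39
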