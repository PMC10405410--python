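# Small end-to-end demo configuration for `charlink run --config`.
seed: 7
outdir: charlink_demo_out
genome:
  n_assembled: 6
  assembled_lengths: 100000
  n_scaffolds: 3
annotation:
  class_counts:
    rRNA: 3
    msrpRNA: 3
    snRNA: 12
    snoRNA: 8
    lncRNA: 40
    mRNA: 60
contacts:
  n_contacts: 12000
chip:
  n_reads: 40000
  effect_size: 6.0
  n_enriched_lncrnas: 1
expression:
  group_fold: 4.0
thresholds:
  min_fragment_len: 18
  cis_window: 10000
  unk_window: 10000
  unk_min_contacts: 20
  alpha: 0.05
  n_background: 4000
  assoc_min_contacts: 50
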