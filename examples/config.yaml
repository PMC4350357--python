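# Example configuration for the accsig CLI.
#
#   accsig all --config examples/config.yaml --seed 1 --out out/
#
# Any omitted option keeps its default; --seed overrides the seed here.

seed: 1

simulate:            # synthetic cohort (defaults = the emulated study design)
  n_pairs: 12
  n_genes: 5000
  n_signature_up: 100
  n_signature_down: 60
  n_fusion_pos: 6
  noise_sd: 0.4
  exon_count: 15
  breakpoint_range: [8, 14]
  n_mirna: 847

analysis:            # pipeline parameters
  alpha: 0.05
  min_fold: 2.0
  mrna_baseline: 50.0
  mirna_baseline: 800.0
  tau: 4.0
  min_delta5: 1.0
  max_delta3: 0.5
  marker: MYB
  k_sd: 2.0
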