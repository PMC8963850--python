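# Example simulation specs for `sorasig simulate cohort|panel --spec FILE`.
# Every key is optional; omitted keys use the generator defaults
# (documented in docs/methods.md).
#
# --- cohort spec (pass to `sorasig simulate cohort`) ---------------------
# group sizes
n_responder: 12
n_poor: 10
# platform: microarray | rnaseq_counts | pcr_ct
platform: microarray
# per-gene log2 effect sizes, responders vs poor responders; genes not
# listed (housekeeping, background) get 0. Omit to use the reference
# screen's estimates for the ten sorafenib targets.
effects:
  FLT1: 1.155
  PDGFRB: 0.273
  KDR: 0.119
# number of null background genes added to the catalog
n_background: 50
# platform noise (see docs/methods.md for units)
microarray_sigma: 0.5     # log2-scale SD of intensities
nb_dispersion: 0.1        # negative-binomial dispersion (rnaseq_counts)
ct_sigma: 0.3             # cycles (pcr_ct)

# --- panel spec (pass to `sorasig simulate panel`) -----------------------
# n_lines: 732
# coupling: 0.043          # score -> log10 IC50 coupling (negative slope)
# noise_sigma: 0.2         # log10 IC50 noise SD
# mutations:               # sparse binary mutations shifting IC50
#   - gene: FLT3
#     n_altered: 11
#     shift_log2: -1.46    # mutants ~2.8-fold more sensitive
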