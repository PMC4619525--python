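# Annotated generator configuration for `samplesim generate --config ...`.
# Every key is optional; omitted keys fall back to the defaults shown here,
# which describe the 89-hospital Dutch landscape.

# Hospitals per stratum.
stratum_sizes:
  academic: 8
  teaching: 28
  general: 53

# Organizational healthcare regions. Either list labels explicitly, or give
# `n_regions: 7` to get synthetic labels R1..R7.
regions:
  - Groningen
  - Leiden
  - Maastricht
  - Nijmegen
  - Noord-Holland
  - Rotterdam
  - Utrecht

# Academic centres are placed one per region; the surplus goes here.
dual_academic_region: Noord-Holland

# Inclusive bed-count ranges per stratum (uniform integer draw).
beds_range:
  academic: [700, 1350]
  teaching: [400, 900]
  general: [150, 600]

# Log-linear count model per product: log(mean) = intercept[type] + slope*beds.
coefficients:
  RBC:
    intercepts: {academic: 7.70, teaching: 7.35, general: 6.93}
    slope: 0.0018
  FFP:
    intercepts: {academic: 6.32, teaching: 5.63, general: 5.03}
    slope: 0.0018
  PLT:
    intercepts: {academic: 6.47, teaching: 5.70, general: 5.11}
    slope: 0.0020

# Shared log-normal hospital effect (raises cross-product correlations).
latent_sd: 0.25

# Per-product case-mix noise (lowers cross-product correlations). The
# defaults are calibrated to Spearman(FFP,RBC) ~ .88, Spearman(PLT,RBC) ~ .92.
product_sd:
  RBC: 0.10
  FFP: 0.35
  PLT: 0.26

# Generation is deterministic given the config and this seed
# (`--seed` on the command line overrides it).
seed: 0
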