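# Example run configuration.
#
# Omit `parameter_file` to use the bundled study parameter tables
# (probabilities derived from visit counts at full precision).  Point it
# at a CSV/JSON in the documented schema to analyse your own strategies.
parameter_file: null
output_dir: results
cost_basis: medication        # "ics" or "medication"
wtp: 287100                   # CNY/QALY; 3x the 2024 per-capita GDP of China (95,700)
pairs:                        # (reference, alternative); reference = cheaper arm
  - [A2, A1]
  - [B1, B2]
  - [A, B]
psa:
  n: 1000
  seed: 0
  cv: 0.3                     # coefficient of variation for costs lacking a published sd
  pair: [A, B]
  wtp_grid: {max: 600000, num: 61}
cohort:
  n_patients: null            # null = observed subgroup sizes (8 / 22 / 21 / 8)
  seed: 0
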