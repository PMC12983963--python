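# The published November-9 field example: explicit second-level weight
# vectors (global scale, so the first-level weights are applied again
# at aggregation and the final normalization absorbs the double
# weighting) together with the expert-scored membership matrices for
# that calf-day.  No judgment matrices are needed; the weights are
# carried verbatim.
evaluation_levels: [none, mild, moderate, severe, extreme]
weight_mode: global
operator: weighted_average
explicit_weights:
  mode: global
  group_order: [B1, B2, B3]
  first_level: [0.54, 0.35, 0.11]
  groups:
    B1: [0.39, 0.11, 0.05]
    B2: [0.14, 0.05, 0.03, 0.13]
    B3: [0.06, 0.03, 0.02, 0.01]
e_matrices:
  B1:
    - [0, 1, 0, 0, 0]
    - [0, 0.9, 0.1, 0, 0]
    - [1, 0, 0, 0, 0]
  B2:
    - [1, 0, 0, 0, 0]
    - [0.8, 0.2, 0, 0, 0]
    - [0.7, 0.3, 0, 0, 0]
    - [1, 0, 0, 0, 0]
  B3:
    - [0.8, 0.2, 0, 0, 0]
    - [0.9, 0.1, 0, 0, 0]
    - [0.6, 0.4, 0, 0, 0]
    - [1, 0, 0, 0, 0]
indicators:
  B1: [temperature_c, humidity_pct, wind]
  B2: [weight_kg, height_cm, diagonal_cm, chest_cm]
  B3: [lying_min, standing_min, rr_per_min, urination_n]
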