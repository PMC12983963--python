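# Farmer-panel judgment matrices for the calf cold-stress hierarchy.
# Same structure as expert.yaml.  Note: the B2 (physiological) matrix
# of this panel is only borderline consistent; weight synthesis on this
# panel requires the force flag.
evaluation_levels: [none, mild, moderate, severe, extreme]
weight_mode: global
operator: weighted_average
panels:
  farmer:
    first_level:
      labels: [B1, B2, B3]
      upper:
        B1/B2: 2
        B1/B3: 4
        B2/B3: 4
    groups:
      B1:
        labels: [b11, b12, b13]
        upper:
          b11/b12: 5
          b11/b13: 7
          b12/b13: 3
      B2:
        labels: [b21, b22, b23, b24]
        upper:
          b21/b22: 3
          b21/b23: 5
          b21/b24: 2
          b22/b23: 2
          b22/b24: 3
          b23/b24: 3
      B3:
        labels: [b31, b32, b33, b34]
        upper:
          b31/b32: 3
          b31/b33: 3
          b31/b34: 4
          b32/b33: 2
          b32/b34: 3
          b33/b34: 2
indicators:
  B1: [temperature_c, humidity_pct, wind]
  B2: [weight_kg, height_cm, diagonal_cm, chest_cm]
  B3: [lying_min, standing_min, rr_per_min, urination_n]
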