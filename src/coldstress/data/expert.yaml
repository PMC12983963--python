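# Expert-panel judgment matrices for the calf cold-stress hierarchy.
# Upper triangles only; reciprocals and unit diagonals are recomputed
# exactly on load.  Groups: B1 environmental (temperature, humidity,
# wind), B2 physiological (weight, height, body diagonal, chest
# circumference), B3 behavioral (lying, standing, respiratory rate,
# urination).
evaluation_levels: [none, mild, moderate, severe, extreme]
weight_mode: global
operator: weighted_average
panels:
  expert:
    first_level:
      labels: [B1, B2, B3]
      upper:
        B1/B2: 4
        B1/B3: 3
        B2/B3: 2
    groups:
      B1:
        labels: [b11, b12, b13]
        upper:
          b11/b12: 2
          b11/b13: 5
          b12/b13: 3
      B2:
        labels: [b21, b22, b23, b24]
        upper:
          b21/b22: 2
          b21/b23: 3
          b21/b24: 3
          b22/b23: 2
          b22/b24: 3
          b23/b24: 2
      B3:
        labels: [b31, b32, b33, b34]
        upper:
          b31/b32: 2
          b31/b33: 2
          b31/b34: 2
          b32/b33: 3
          b32/b34: 4
          b33/b34: 2
indicators:
  B1: [temperature_c, humidity_pct, wind]
  B2: [weight_kg, height_cm, diagonal_cm, chest_cm]
  B3: [lying_min, standing_min, rr_per_min, urination_n]
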