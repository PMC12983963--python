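# Illustrative trapezoidal membership breakpoints, NOT elicited from
# any survey: five severity-level centers per indicator (none -> extreme),
# forming a hat-function fuzzy partition over the declared domain.
# Decreasing center sequences mark lower-is-more-severe indicators.
# Intended for exercising the pipeline on synthetic cohorts; replace
# with expert-derived functions for any real assessment.
membership_centers:
  centers:
    temperature_c: [10, 0, -10, -18, -26]
    humidity_pct: [40, 55, 70, 80, 90]
    wind: [0, 5, 10, 20, 30]
    weight_kg: [80, 60, 45, 38, 32]
    height_cm: [95, 85, 78, 72, 65]
    diagonal_cm: [85, 75, 65, 58, 50]
    chest_cm: [110, 95, 85, 78, 70]
    lying_min: [700, 900, 1050, 1200, 1350]
    standing_min: [700, 500, 380, 250, 100]
    rr_per_min: [50, 44, 38, 32, 26]
    urination_n: [0, 1, 2, 3, 5]
  domains:
    temperature_c: [-60, 45]
    humidity_pct: [0, 100]
    wind: [0, 80]
    weight_kg: [15, 150]
    height_cm: [50, 120]
    diagonal_cm: [30, 110]
    chest_cm: [50, 140]
    lying_min: [0, 1440]
    standing_min: [0, 1440]
    rr_per_min: [1, 100]
    urination_n: [0, 20]
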