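{
  "seed": 20260906,
  "phantom": {
    "grid_shape": [90, 96, 96],
    "spacing": [2.5, 0.871, 0.871],
    "planted_cobb": 38.6
  },
  "cohort": {
    "n_cases": 433,
    "cobb_mean": 38.6,
    "cobb_sd": 13.5,
    "per_muscle_loading": {"paraspinal": 0.42, "psoas": 0.23, "quadratus_lumborum": 0.33},
    "per_muscle_fat_mean": {"paraspinal": 15.0, "psoas": 5.0, "quadratus_lumborum": 14.0},
    "per_muscle_fat_sd": {"paraspinal": 9.0, "psoas": 2.5, "quadratus_lumborum": 7.0},
    "n_surgery": 10,
    "n_atrophy": 5,
    "n_fracture": 52,
    "n_transitional": 25
  },
  "raters": {
    "k_raters": 4,
    "per_rating_error_sd": 3.69
  },
  "fat_quant": {
    "fat_threshold_hu": -20.0,
    "merge_bilateral": true
  },
  "exclusions": {
    "exclude_surgery": true,
    "exclude_atrophy": true,
    "atrophy_threshold": 50.0
  },
  "bootstrap": {
    "n_bootstrap": 500,
    "level": 0.95
  }
}
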