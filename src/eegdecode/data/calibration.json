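{
  "comment": "Generator effect sizes and cohort geometry fixed by a pilot sweep; the specificity and recovery suites assert at these study conditions.",
  "cohort": {
    "n_participants": 5,
    "n_categories": 2,
    "trials_per_category": 24,
    "n_electrodes": 8,
    "fs": 250.0
  },
  "window": {"width_ms": 50.0, "step_ms": 20.0},
  "effect_size": {
    "mean": 1.0,
    "variance": 1.0,
    "frequency": 2.0,
    "multiscale": 1.0
  },
  "informative_band_ms": [50.0, 350.0],
  "behavior": {
    "n_participants": 16,
    "n_categories": 2,
    "trials_per_category": 24,
    "n_electrodes": 8,
    "fs": 250.0,
    "code": "mean",
    "effect_size": 1.5,
    "rt_link": {"intercept": 1146.0, "slope": 400.0, "noise_sd": 20.0}
  },
  "null_cohort": {
    "n_participants": 10,
    "n_categories": 4,
    "trials_per_category": 30,
    "n_electrodes": 16,
    "fs": 250.0
  }
}
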