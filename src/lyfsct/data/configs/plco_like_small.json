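{
  "age_bands": [
    [
      55,
      59,
      0.3
    ],
    [
      60,
      64,
      0.3
    ],
    [
      65,
      69,
      0.25
    ],
    [
      70,
      74,
      0.15
    ]
  ],
  "calendar_years": [
    1993,
    2001
  ],
  "entry_spread_years": 8.0,
  "horizon_years": 16.0,
  "n": 10000,
  "outcome_mode": "full",
  "race_mix": {
    "african_american": 0.06,
    "asian_american": 0.04,
    "hispanic_american": 0.04,
    "white": 0.86
  },
  "seed": 19930,
  "weights": "unit"
}
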