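{
  "calendar_years": [
    2015,
    2018
  ],
  "entry_spread_years": 0.0,
  "horizon_years": 5.0,
  "n": 5000,
  "outcome_mode": "none",
  "seed": 20150,
  "weights": "gamma"
}
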