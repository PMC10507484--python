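{
  "baseline": {
    "family": "gompertz",
    "level": 0.00028,
    "shape": 0.05
  },
  "coding_scheme": "lcdrat",
  "coefficients": {
    "bmi_le_18_5": 0.371563556432483,
    "education": -0.09431067947124129,
    "emphysema": 0.5538851132264376,
    "family_history_lc": 0.3576744442718159,
    "female": -0.1743533871447778,
    "gt_1_pack_per_day": 0.22314355131420976,
    "log_age": 6.035840219827535,
    "log_bmi": -0.7339691750802004,
    "log_quit_years": -0.3856624808119846,
    "log_years_smoked": 0.34358970439007686,
    "pack_years_30_to_40": 0.5423242908253617,
    "pack_years_40_to_50": 0.7371640659767196,
    "pack_years_ge_50": 0.883767540168595,
    "three_annual_ct_screens": -0.2231435513142097
  },
  "includes_race": false,
  "outcome": "lung_cancer_death"
}
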