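{
  "baseline": {
    "family": "gompertz",
    "level": 0.00027,
    "shape": 0.05
  },
  "coding_scheme": "lcdrat",
  "coefficients": {
    "bmi_le_18_5": 0.35065687161316933,
    "education": -0.09431067947124129,
    "emphysema": 0.5538851132264376,
    "family_history_lc": 0.35065687161316933,
    "female": -0.1743533871447778,
    "gt_1_pack_per_day": 0.23901690047049992,
    "log_age": 6.045952732392052,
    "log_bmi": -0.7985076962177716,
    "log_quit_years": -0.37106368139083207,
    "log_years_smoked": 0.3293037471426003,
    "pack_years_30_to_40": 0.5538851132264376,
    "pack_years_40_to_50": 0.7466879474879751,
    "pack_years_ge_50": 0.8960880245566357,
    "race_african_american": 0.3920420877760237,
    "race_asian_or_other": -0.4155154439616658,
    "race_hispanic": -0.37106368139083207,
    "three_annual_ct_screens": -0.2231435513142097
  },
  "includes_race": true,
  "outcome": "lung_cancer_death"
}
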