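{
  "baseline": {
    "family": "gompertz",
    "level": 0.0019,
    "shape": 0.085
  },
  "coding_scheme": "acm",
  "coefficients": {
    "angina": 0.0,
    "bmi_18_5_to_20": 0.27763173659827955,
    "bmi_25_to_30": -0.19845093872383832,
    "bmi_30_to_35": -0.13926206733350766,
    "bmi_gt_35": 0.02955880224154443,
    "bmi_le_18_5": 0.6471032420585384,
    "calendar_year": -0.020202707317519466,
    "chronic_bronchitis": 0.10436001532424286,
    "coronary_heart_disease": 0.12221763272424911,
    "diabetes": 0.37843643572024505,
    "education": -0.07257069283483537,
    "emphysema": 0.44468582126144574,
    "female": -0.31471074483970024,
    "heart_disease": 0.13976194237515863,
    "hypertension": 0.1570037488096647,
    "kidney_failure": 0.34358970439007686,
    "liver_condition": 0.5247285289349821,
    "log_cigarettes_per_day": 0.0769610411361284,
    "log_quit_years": -0.19845093872383832,
    "prior_cancer": 0.2151113796169455,
    "prior_heart_attack": 0.22314355131420976,
    "prior_stroke": 0.26236426446749106,
    "special_equipment": 0.5187937934151675,
    "sqrt_pack_years": 0.03922071315328133
  },
  "includes_race": false,
  "outcome": "all_cause_mortality"
}
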