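{
  "baseline": {
    "family": "gompertz",
    "level": 0.0018,
    "shape": 0.085
  },
  "coding_scheme": "acm",
  "coefficients": {
    "angina": 0.009950330853168092,
    "bmi_18_5_to_20": 0.29266961396282004,
    "bmi_25_to_30": -0.19845093872383832,
    "bmi_30_to_35": -0.13926206733350766,
    "bmi_gt_35": 0.01980262729617973,
    "bmi_le_18_5": 0.6523251860396901,
    "calendar_year": -0.020202707317519466,
    "chronic_bronchitis": 0.10436001532424286,
    "coronary_heart_disease": 0.12221763272424911,
    "diabetes": 0.3852624007906449,
    "education": -0.07257069283483537,
    "emphysema": 0.45107561936021673,
    "female": -0.3285040669720361,
    "heart_disease": 0.13976194237515863,
    "hypertension": 0.14842000511827322,
    "kidney_failure": 0.34358970439007686,
    "liver_condition": 0.5187937934151675,
    "log_cigarettes_per_day": 0.08617769624105241,
    "log_quit_years": -0.19845093872383832,
    "prior_cancer": 0.2151113796169455,
    "prior_heart_attack": 0.22314355131420976,
    "prior_stroke": 0.25464221837358075,
    "race_african_american": 0.19885085874516517,
    "race_asian_or_other": -0.2876820724517809,
    "race_hispanic": -0.13926206733350766,
    "special_equipment": 0.5068176023684519,
    "sqrt_pack_years": 0.03922071315328133
  },
  "includes_race": true,
  "outcome": "all_cause_mortality"
}
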