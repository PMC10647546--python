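{
  "description": "Element positivity counts among RD-assessed PICU patients, stratified by malnutrition status (none vs any).",
  "n_no_malnutrition": 181,
  "n_any_malnutrition": 69,
  "severity_counts": {"none": 181, "mild": 27, "moderate": 24, "severe": 18},
  "any_positive_screen": {"no_malnutrition": 175, "any_malnutrition": 68},
  "elements": {
    "enteral_nutrition": {"no_malnutrition": 146, "any_malnutrition": 56},
    "food_allergies_2plus": {"no_malnutrition": 4, "any_malnutrition": 2},
    "intubation": {"no_malnutrition": 64, "any_malnutrition": 20},
    "parenteral_nutrition": {"no_malnutrition": 29, "any_malnutrition": 27},
    "rd_identified_risk": {"no_malnutrition": 28, "any_malnutrition": 14},
    "pnst_positive": {"no_malnutrition": 13, "any_malnutrition": 24},
    "anthropometric_flag": {"no_malnutrition": 32, "any_malnutrition": 40},
    "intake_lt50_3d": {"no_malnutrition": 7, "any_malnutrition": 3},
    "npo_gt3d": {"no_malnutrition": 3, "any_malnutrition": 0},
    "weight_loss_ge5pct": {"no_malnutrition": 3, "any_malnutrition": 0}
  }
}
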