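{
  "description": "Element positivity counts among PICU patients never assessed by a dietitian (true nutrition status unknown).",
  "n_total": 918,
  "any_positive_screen": 385,
  "elements": {
    "enteral_nutrition": 295,
    "food_allergies_2plus": 14,
    "intubation": 102,
    "parenteral_nutrition": 0,
    "rd_identified_risk": 0,
    "pnst_positive": 27,
    "anthropometric_flag": 121,
    "intake_lt50_3d": 6,
    "npo_gt3d": 2,
    "weight_loss_ge5pct": 2
  }
}
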