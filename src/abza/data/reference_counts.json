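{
  "description": "Published contingency counts of the 108-patient MCAO endovascular-treatment cohort: favorable outcome = 90-day mRS <= 2, good collaterals = ABZA grade > 2.",
  "outcome_by_collateral": {
    "good_collateral_favorable": 28,
    "good_collateral_unfavorable": 8,
    "poor_collateral_favorable": 9,
    "poor_collateral_unfavorable": 63
  },
  "toast_by_collateral": {
    "laa_good": 23,
    "laa_total": 44,
    "ce_good": 10,
    "ce_total": 59
  },
  "cohort": {
    "n": 108,
    "favorable": 37
  },
  "reported": {
    "sensitivity_pct": 75.7,
    "specificity_pct": 88.7,
    "youden": 0.644,
    "prevalence_pct": 34.3,
    "favorable_in_good_pct": 78,
    "favorable_in_poor_pct": 13,
    "good_in_laa_pct": 52,
    "good_in_ce_pct": 17,
    "grade3_boundary_deg": 57.5
  }
}
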