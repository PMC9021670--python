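{
  "national_population": 818289,
  "sample_population": 242236,
  "all_codes": {
    "sample_cases": 191174, "sample_cost_eur": 770368090,
    "national_cases": 645798, "national_cost_eur": 2602353631
  },
  "included_117": {
    "sample_cases": 157322, "sample_cost_eur": 632505610,
    "sample_case_share_pct": 82.29, "sample_cost_share_pct": 82.10,
    "national_cases": 531444, "national_cost_eur": 2136645184
  },
  "nhs_58": {
    "sample_cases": 79979, "sample_cost_eur": 281713203,
    "case_share_of_all_pct": 41.84, "case_share_of_included_pct": 50.84,
    "cost_share_of_all_pct": 36.57, "cost_share_of_included_pct": 44.54,
    "national_cases": 270174, "national_cost_eur": 951654564
  },
  "avoidable": {
    "sample_cases": 65133, "sample_cost_eur": 227439230,
    "national_cases": 219955, "national_cost_eur": 768304547
  }
}
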