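{
  "category_counts": {
    "high": 0,
    "low": 1,
    "moderate": 0,
    "not_specified": 1
  },
  "config": "example-structured+dx+text",
  "exclusion_reasons": {
    "viral_hepatitis_dx": 1
  },
  "mean_risk_difference_by_year": {
    "2014": 0.16172377634576324,
    "2015": 0.1683369359410959,
    "2016": 0.16611030210240285,
    "2017": 0.17206734997554685,
    "2018": 0.17905337635347346,
    "2019": 0.13738297171986869,
    "2020": 0.14673043827546656,
    "2021": 0.15244407843647395
  },
  "n_eligible": 2,
  "n_excluded": 1
}
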