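# Alcohol usage categories with weekly-serving bounds, anchored on the THL
# (Finnish Institute for Health and Welfare) risk-drinking limits:
# about 23 weekly servings for men and 12 for women mark hazardous use.
# The exact intermediate bins are artifact-chosen defaults and fully
# configurable; the heavy-category floors are the THL limits and the
# ceiling is the risk model's maximum substitution value (49).
categories:
  none:
    male: [0, 0]
    female: [0, 0]
  moderate:
    male: [1, 13]
    female: [1, 6]
  at_risk:
    male: [14, 22]
    female: [7, 11]
  heavy:
    male: [23, 49]
    female: [12, 49]
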