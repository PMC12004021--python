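# Diagnosis-code to risk-evidence mapping.
#
# Codes are the alcohol- and smoking-related ICD-10 / ICPC-2 codes observed
# in Finnish primary and specialist care records.  A trailing "X" in a
# pattern matches any code in the family (e.g. "F10.2X" covers F10.20,
# F10.24, ...).  Effects:
#   alcohol_heavy - evidence of hazardous drinking; floors the weekly
#                   serving count at the THL risk limit (23 men / 12 women)
#   smoker_true   - exact smoking-status evidence for the risk model
entries:
  - {system: "ICD-10", code: "F10.09", effect: alcohol_heavy}   # unspecified alcohol intoxication
  - {system: "ICD-10", code: "F10.1",  effect: alcohol_heavy}   # alcohol abuse
  - {system: "ICD-10", code: "F10.2X", effect: alcohol_heavy}   # alcohol dependence family
  - {system: "ICD-10", code: "F10.39", effect: alcohol_heavy}   # withdrawal symptoms
  - {system: "ICPC-2", code: "P15",    effect: alcohol_heavy}   # chronic alcohol abuse
  - {system: "ICPC-2", code: "P16",    effect: alcohol_heavy}   # acute alcohol abuse
  - {system: "ICD-10", code: "Z72.0",  effect: smoker_true}     # tobacco use
  - {system: "ICPC-2", code: "P17",    effect: smoker_true}     # tobacco abuse
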