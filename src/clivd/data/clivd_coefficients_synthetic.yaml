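# SYNTHETIC coefficient transcription for the CLivD 10-year risk function.
#
# The published coefficient values live in a journal supplement that is not
# redistributed with this package, so this file ships a synthetic
# calibration: the functional form (Cox-type 10-year risk
# 1 - S0 ** exp(linear_predictor)), the lab/nonlab variant split and the
# directions of effect (age, male sex, smoking, weekly alcohol servings,
# waist-hip ratio, diabetes and GGT all increase risk) follow the published
# model; the magnitudes are a one-time calibration to plausible general-
# population epidemiology, documented in docs/methods.md.  Replace this file
# with a faithful transcription to score with the published model; the code
# never hard-codes coefficients.
provenance: >
  Synthetic calibration (artifact-authored). Effect directions match the
  published CLivD risk factors; magnitudes are NOT the published values.

cutoffs:
  low: 0.05
  high: 0.10

age_window:
  min: 40
  max: 70

models:
  nonlab:
    baseline_survival_10y: 0.9988
    centering:
      age_years: 55.0
      whr: 0.90
    coefficients:
      male: 0.60
      age_per_year: 0.045
      smoker: 0.75
      alcohol_per_weekly_serving: 0.035
      whr_per_unit: 6.0
      diabetes: 0.60
  lab:
    baseline_survival_10y: 0.9988
    centering:
      age_years: 55.0
      whr: 0.90
      log_ggt: 3.6888794541139363  # ln(40 U/L)
    coefficients:
      male: 0.60
      age_per_year: 0.045
      smoker: 0.75
      alcohol_per_weekly_serving: 0.035
      whr_per_unit: 6.0
      diabetes: 0.60
      log_ggt: 0.50
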