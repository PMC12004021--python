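# Methods

## Problem and approach

The CLivD (Chronic Liver Disease) score predicts an individual's 10-year
risk of severe liver disease from sex, age, smoking status, weekly alcohol
servings, diabetes and waist-hip ratio (WHR), optionally adding the GGT
laboratory value (*lab* variant; the *nonlab* variant is used when GGT is
unavailable). Applying such a cross-sectional score to longitudinal
electronic health records raises two problems this package addresses:

1. **Temporal validity.** Measurements are scattered in time, so each is
   given a validity window (a *lifecycle*). Two presets are provided:
   `one_year` (valid for 365 days after measurement) and `infinite` (valid
   until the next measurement of the same parameter, or to the end of
   history). Diagnoses accumulate with infinite validity under both
   presets. Validity is forward-only by default — a measurement never
   informs dates before it was taken — because backward validity would let
   future observations alter past risk assessments; a `lookback` duration
   is available for users who want symmetric windows.

2. **Missing inputs.** Rather than imputing, each missing input is
   substituted by its two extreme defaults — WHR (0.7, 1.3), smoking
   (false, true), alcohol (0, 49 servings/week), diabetes (false, true) —
   and the score is evaluated at both ends, producing a **risk interval**
   (minimum risk, maximum risk). The interval's width measures the
   precision of the assessment; a fully observed patient gets width 0.
   Missing GGT switches both ends to the nonlab variant. A missing
   fasting glucose / diabetes diagnosis is read as *no diabetes* by
   default (`missing_diabetes_unknown=False`), following the
   interpretation that undocumented diabetes is absent; setting the flag
   restores the (false, true) interval behaviour.

Risk intervals are mapped to categories against cutoffs (low 5%, high
10%), in this decision order: **high** if risk_min ≥ 10%; else **low** if
risk_max < 5%; else **moderate** if risk_min > 5%; else **not specified**
(the interval straddles a cutoff). Boundary cases not covered by the
strict/non-strict cutoff symbols (e.g. risk_min exactly 5%) fall to
not-specified — the honest default when the category is genuinely
ambiguous. Cutoffs, the eligible age window [40, 70] (inclusive; the
boundary readings of the published criteria differ by one year and the
input-default table's 40/70 bounds were followed) and the diabetes code
set (ICD-10 E10–E14, ICPC-2 T89/T90) are configurable.

### Exclusion screening

Patients are excluded at a query date when: age is outside [40, 70]; any
liver-disease diagnosis (ICD-10 K70–K77 families, prefix-matched, or
C22.0) is active; any chronic viral hepatitis (B18.x) is active; or the
current-abstainer-with-prior-use criterion fires. The abstainer criterion
is ambiguous at the code level — F10.2x dependence codes identify
abstainers in the original score's derivation but also serve as
heavy-drinking evidence — so by default (`abstainer_mode="text_confirmed"`)
F10.2x triggers exclusion only when abstinence text evidence co-occurs,
and otherwise feeds the alcohol approximation; `code_only` makes the code
alone sufficient.

## The risk function and its coefficients

The score is a Cox-type transform `risk = 1 − S0 ** exp(lp)` of a linear
predictor in centered covariates (age centered at 55 years, WHR at 0.90,
log-GGT at ln 40 U/L). **The shipped coefficient file is a labelled
synthetic calibration**, not the published values (which live in a journal
supplement not redistributed here): effect directions match the published
risk factors (all coefficients positive), and magnitudes were fixed once,
analytically, so that the implementation reproduces the qualitative
structure reported for this kind of population:

* the all-missing maximum risk exceeds the 5% cutoff for every eligible
  age/sex (structured data alone categorizes almost no one);
* a person with text-confirmed non-smoking and non-drinking stays below
  5% maximum risk even at the WHR ceiling 1.3 (text enrichment identifies
  low-risk individuals);
* the minimum risk at the WHR floor 0.7 stays below 10% for any realistic
  combination of the other inputs (no high-risk calls are possible while
  WHR is missing);
* once WHR is observed, elevated values push the minimum risk past 10%
  (high-risk calls appear with WHR availability).

The resulting values are S0 = 0.9988 and per-unit weights 0.60 (male),
0.045 (year of age), 0.75 (smoker), 0.035 (weekly serving), 6.0 (WHR
unit), 0.60 (diabetes), 0.50 (ln GGT). Users scoring with the published
model should replace `src/clivd/data/clivd_coefficients_synthetic.yaml`
with a faithful transcription; the code never hard-codes coefficients, and
the loader validates completeness and finiteness. `risk_interval` asserts
min ≤ max and raises a consistency error otherwise, guarding against a
non-monotone transcription.

## Evidence enrichment

Structured records rarely contain the behavioural inputs, so two auxiliary
sources contribute *bounded* evidence, merged with precedence
**structured > text > diagnosis** (professionally recorded exact values
beat narrative findings, which beat coarse code approximations; within a
source the most recent valid finding wins, same-date ties to the last
record in file order):

* **Diagnosis codes.** Hazardous-drinking codes (F10.09, F10.1, the
  F10.2x family, F10.39, P15, P16) floor weekly servings at the Finnish
  risk-drinking limits — 23 for men, 12 for women — with the substitution
  ceiling 49. Tobacco codes (Z72.0, P17) pin smoking to true, which is
  exact for this model (it ignores quantity). Code patterns support
  family prefixes (`F10.2X`).
* **Free text.** A case-insensitive regex keyword search over Finnish
  narrative converts phrases to findings: a negation stem
  (`ei\s*\w*\s*alkohol`) yields the *none* category, heavy-use and
  withdrawal/intoxication stems (`runsa\w*\s*alkohol\w*`,
  `vieroitus|vierotus|päihtymys|putki|katkaisu`) yield *heavy*, a bare
  use stem yields *moderate*; smoking stems map to positive/negative
  status. A positive match whose span overlaps a negation match is
  suppressed. Alcohol categories carry sex-specific (min, max) serving
  bounds (none 0–0; moderate 1–13 / 1–6; at-risk 14–22 / 7–11; heavy
  23–49 / 12–49); the heavy floors are the published risk limits, the
  intermediate bins are package defaults, all configurable. The smoking
  keyword set is likewise a package default, not a published list.

Text findings age like measurements (habits change): a finding is valid
at a query date exactly when a measurement on its date would be.
Because every evidence bound lies inside the substitution defaults and
the score is monotone, enrichment can only narrow a risk interval.

## WHR availability scenarios

WHR is absent from structured data, so its effect is simulated: values
are drawn from sex-specific normals (mean 0.96 men / 0.84 women,
variance 0.07) and injected as `source="simulated"` measurements under
three modes — *document coverage* (each distinct event date independently
carries a WHR with probability 0.5% or 10%, the two study coverages,
applied per event date as the closest reading of per-document coverage),
and two *self-report* modes (one value per patient at the first date at
or after age 40, exact or categorical).

Two numerical points are deliberate:

* **Variance read literally.** Variance 0.07 means SD ≈ 0.265, which is
  physiologically wide; it is taken at face value (a `variance_is_sd`
  switch reads it as an SD instead — flagged, not silently corrected).
  Draws are truncated to the plausibility window (0.3, 2.0) by
  resampling; under the literal variance this truncation shifts sample
  means above nominal by ≈ +0.005 (men) and ≈ +0.013 (women) — the
  analytic truncated means are 0.9647 and 0.8534. Tests compare sample
  means to the analytic truncated means at Monte-Carlo precision and to
  the nominal parameters within this known bias.
* **Categorical schemes.** A categorical answer replaces the exact value
  by its bin's (min, max). Default edges are *nested* — 3-bin (0.85,
  1.00), 5-bin (0.80, 0.85, 1.00, 1.10) — so every 5-bin interval sits
  inside a 3-bin interval and categorization refines monotonically.
  Outer bins clamp to the substitution defaults (0.7, 1.3); a value
  outside the clamp extends its own bin just enough to enclose it, which
  preserves the enclosure guarantee (bounds always contain the value) at
  the cost of the nested-in-defaults property for extreme values. A
  consequence worth stating: with the literal-variance distribution a
  non-trivial fraction of simulated WHR values falls outside (0.7, 1.3),
  and for those patients an *observed* WHR legitimately moves the risk
  interval outside the default envelope — the never-widens containment
  property holds for in-band observations, while cohort-level mean
  widths still decrease with WHR availability.

## Synthetic cohort generator

The generator emulates the marginal statistics of the source repository
so every stage is testable without restricted data. Defaults are the
study conditions:

* **Occurrence histograms.** Per-parameter structured-measurement counts
  per patient are drawn from the published occurrence-class proportions
  (classes 0 / 1 / 2–5 / 6–10 / 11–15 / >15 over a 96,200-patient
  reference; e.g. ≥1 GGT for 4.48% of patients, ≥1 fasting glucose for
  12.14%). Within-class counts are uniform over the class range (the
  source gives only class totals; the open class caps at 20). WHR,
  structured alcohol use and hip circumference never occur, mirroring
  their absence from structured data.
* **Latent habits.** True heavy-drinker (25%), smoker (20%) and diabetic
  (8%) status is drawn first and drives diagnosis emission, text
  snippets and measurement values coherently, enabling end-to-end
  recovery tests. Per-code diagnosis rates are the published counts
  scaled by the reference cohort size, divided by the latent prevalence
  (so marginal code rates match the source); a small artifact-chosen
  rate of liver/hepatitis/cancer codes exercises the exclusion paths.
* **Text.** Habit-conditional Finnish snippets embed the keyword stems
  the extractor searches for (emission rates 30–35%, artifact-chosen),
  plus neutral keyword-free notes (Poisson, mean 2 per patient).
  Document dates are uniform over 2014-01-01..2022-06-30; ages uniform
  18–85 at the range start, sexes balanced.
* **Values.** Measurement value distributions (heights, weights, GGT
  log-normal around 25 U/L, glucose bimodal by diabetic status, ...) are
  artifact-chosen plausible adult defaults — the source tables give
  occurrences, not values.

What passing tests therefore do and do not show: they demonstrate the
pipeline's logic, determinism and marginal calibration against the
documented structure, not performance on real records — real narrative is
far messier than the embedded snippets, real measurement histories are
temporally clustered rather than uniform, and habit–age–sex correlations
are absent here.

## Problem sizes and numerical choices

Cohort-level tests use 300–1,000 patients (5,000 for histogram
goodness-of-fit, chi-square with small-expectation pooling at p > 0.001);
distribution-recovery checks use 20,000–100,000 draws with 3–4σ
Monte-Carlo tolerances; the acceptance script uses 100,000 draws and a
3,000-patient cohort (≈ 15,000 distinct event dates). The yearly grid
evaluates each year on Dec 31 (the study plots per-year averages without
stating an evaluation date). Same-date ties resolve to the last record in
file order. Floating-point comparisons in interval-containment checks use
a 1e-12 slack. Per-person categorization uses the narrowest interval over
the patient's eligible grid dates, ties to the latest date; yearly series
use per-date eligibility (a patient enters the denominator the year they
turn 40), and a year with no eligible patients reports an absent mean,
never zero.

## Known limitations

* The coefficient file is a synthetic calibration; absolute risks and
  category counts are not comparable to published population figures.
* Regex phenotyping handles only the configured stems and span-overlap
  negation; no scope parsing, no temporality ("smoked 10 years ago"
  reads as positive).
* The generator draws event dates independently per parameter and leaves
  habits independent of age and sex.
* Document-coverage simulation treats one calendar date as one document;
  multiple same-day documents are not distinguished.
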