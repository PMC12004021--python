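# clivd — interval-valued liver-disease risk from incomplete EHR timelines

`clivd` implements the CLivD (Chronic Liver Disease) 10-year risk score
for longitudinal electronic-health-record data in which most of the
score's inputs are missing most of the time. It is aimed at
biostatisticians and health-data engineers studying the feasibility of
automated risk detection on national-repository–style data: instead of
imputing missing inputs, it propagates them as intervals and quantifies
how each additional data source narrows the result.

## The method

The score is a Cox-type 10-year risk

```
risk = 1 − S₀^exp(lp),
lp   = β_male·𝟙[male] + β_age·(age − 55) + β_smk·𝟙[smoker]
       + β_alc·(servings/week) + β_whr·(WHR − 0.90) + β_dm·𝟙[diabetes]
       [+ β_ggt·(ln GGT − ln 40)]          (lab variant only)
```

For each patient and query date the pipeline:

1. resolves which measurements are valid under a **parameter lifecycle**
   (`one_year` or `infinite`; diagnoses always accumulate);
2. enriches smoking and alcohol inputs from ICD-10/ICPC-2 codes and from
   Finnish free text via regex keyword search (precedence
   structured > text > diagnosis) — e.g. a hazardous-drinking code floors
   weekly servings at 23 (men) / 12 (women);
3. screens the exclusion criteria (age outside 40–70, liver disease
   K70–K77/C22.0, viral hepatitis B18, current abstainer with prior use);
4. substitutes the extreme defaults for whatever is still missing — WHR
   (0.7, 1.3), smoking (false, true), alcohol (0, 49), diabetes
   (false, true); missing GGT selects the non-GGT variant — and evaluates
   the score at both ends, yielding a **risk interval**
   (risk_min, risk_max);
5. categorizes the interval against 5%/10% cutoffs: **high** if
   risk_min ≥ 10%, **low** if risk_max < 5%, **moderate** if
   risk_min > 5%, otherwise **not specified**.

A synthetic cohort generator reproduces the documented marginal structure
of the source repository (per-parameter occurrence histograms, diagnosis
code rates, habit-conditional Finnish text snippets), and a WHR scenario
simulator injects waist-hip-ratio data (absent from structured records) at
configurable coverage — N(0.96, 0.07) for men, N(0.84, 0.07) for women —
exactly or as 3-/5-category questionnaire bins.

**Note:** the shipped coefficient file is a *labelled synthetic
calibration* with the published effect directions, not the published
coefficient values (see `docs/methods.md`); replace
`src/clivd/data/clivd_coefficients_synthetic.yaml` with a faithful
transcription to score with the published model.

## Worked example

Score the committed three-patient example cohort
(`tests/data/example_cohort.jsonl`, format in `docs/format.md`):

```sh
$ clivd score tests/data/example_cohort.jsonl --patient-id EX-002 --date 2020-12-31
EX-002 at 2020-12-31: risk [0.0005, 0.0182] width 0.0177 -> low

$ clivd score tests/data/example_cohort.jsonl --patient-id EX-002 --date 2020-12-31 --no-enrichment
EX-002 at 2020-12-31: risk [0.0005, 0.1947] width 0.1942 -> not_specified

$ clivd score tests/data/example_cohort.jsonl --patient-id EX-001 --date 2020-12-31
EX-001 at 2020-12-31: risk [0.0036, 0.2793] width 0.2757 -> not_specified

$ clivd score tests/data/example_cohort.jsonl --patient-id EX-003 --date 2020-12-31
EX-003 excluded at 2020-12-31: viral_hepatitis_dx
```

EX-002's notes say "Ei käytä alkoholia" and "Ei tupakoi" (does not drink,
does not smoke): with text enrichment her maximum risk drops from 19.5%
to 1.8% and she becomes classifiable as low risk — with structured data
alone the interval straddles the 5% cutoff and no call can be made.
EX-001 smokes and carries an alcohol-abuse code, so his minimum risk
rises but the missing WHR keeps the interval wide (27.6 percentage
points). EX-003 has a chronic-hepatitis diagnosis and is excluded.

Cohort-level runs come from a YAML config:

```yaml
# pipeline.yaml
name: demo
lifecycle: infinite          # or one_year
use_diagnoses: true
use_text: true
generate: {n_patients: 1000, seed: 1}
# whr_scenario: {mode: document_coverage, coverage_fraction: 0.10}
```

```sh
clivd run pipeline.yaml --out-dir out/
clivd report out/report.json
```

which prints per-category counts, exclusion tallies and the mean
risk-interval width per calendar year (the precision series: adding
diagnosis, text and WHR sources makes it shrink).

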