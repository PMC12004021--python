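# Event-stream record format

A cohort is a UTF-8 JSON Lines file: one JSON object per line, no blank
lines required, order canonicalized on write (patients by `patient_id`;
each patient's demographics line first, then events by date, same-date
events in file order — downstream tie-breaks give the *last* record on a
date precedence).

## Record types

Every record carries `type` and `patient_id`.

### `patient` — demographics (exactly one per patient)

```json
{"type": "patient", "patient_id": "SYN-000001", "sex": "male", "birth_date": "1962-04-17"}
```

* `sex`: `male` | `female`
* `birth_date`: ISO-8601 calendar date, strictly before every event date

### `measurement` — a dated observation

```json
{"type": "measurement", "patient_id": "SYN-000001", "date": "2015-03-01", "parameter": "weight", "value": 81.5}
```

* `parameter` (unit): `fasting_glucose` (mmol/L), `height` (cm), `weight`
  (kg), `bmi` (kg/m²), `waist_circumference` (cm), `hip_circumference`
  (cm), `ggt` (U/L), `whr` (ratio, open interval 0.3–2.0),
  `smoking_status` (boolean), `alcohol_servings_per_week` (count)
* `value`: non-negative number, or a boolean for `smoking_status`
* `source` (optional): `structured` (default) or `simulated` for
  scenario-injected values

### `diagnosis` — a dated coded diagnosis

```json
{"type": "diagnosis", "patient_id": "SYN-000001", "date": "2016-01-10", "system": "ICD-10", "code": "F10.1"}
```

* `system`: `ICD-10` (dotted codes like `F10.1`, `K70`, `C22.0`) or
  `ICPC-2` (letter + two digits, like `P15`)

### `text` — a dated free-text note (Finnish clinical narrative)

```json
{"type": "text", "patient_id": "SYN-000001", "date": "2017-06-02", "text": "Ei käytä alkoholia."}
```

* `text`: non-empty string

## Guarantees

* `read_events` → `write_events` round-trips byte-identically on any
  canonically written file.
* Dates are whole calendar days; there is no intra-day ordering.
* A committed example lives at `tests/data/example_cohort.jsonl`.
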