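"""Synthetic cohort generator emulating the national-repository data's
marginal statistics, so the whole pipeline is testable without access to
the restricted registry.

What it emulates (defaults are the study conditions):

* per-parameter structured-measurement occurrence histograms over patient
  history, using the published occurrence-class counts (N=96,200): classes
  {0, 1, 2-5, 6-10, 11-15, >15} per parameter — e.g. ~4.5% of patients
  have at least one GGT and ~12% at least one fasting glucose; WHR,
  structured alcohol use and hip circumference do not occur at all;
* alcohol- and smoking-related diagnosis code rates (per-code counts
  scaled by the 96,200 cohort size), driven by latent heavy-drinker /
  smoker status so that codes and text agree within a patient;
* document dates uniform over 2014-01-01 .. 2022-06-30 and an adult
  age/sex structure;
* Finnish text snippets embedding the keyword stems the text analysis
  searches for, emitted conditionally on the latent habits.

Measurement *values* (heights, weights, GGT levels, ...) are artifact-
chosen plausible adult distributions — the source tables give occurrence
counts, not values.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, DomainError
from .records import (
    CodeSystem,
    DiagnosisEvent,
    EventStream,
    MeasurementEvent,
    Parameter,
    Patient,
    Sex,
    TextEvent,
    validate_stream,
)

__all__ = ["CohortConfig", "generate_cohort", "occurrence_histogram", "OCCURRENCE_CLASSES"]

N_REFERENCE = 96_200  # reference cohort size behind the default rates

#: Occurrence classes over a patient's history, in order.
OCCURRENCE_CLASSES = ("0", "1", "2-5", "6-10", "11-15", ">15")

_CLASS_RANGES = {"0": (0, 0), "1": (1, 1), "2-5": (2, 5), "6-10": (6, 10), "11-15": (11, 15), ">15": (16, 20)}

# Published occurrence-class counts per structured parameter (N=96,200).
_TABLE_COUNTS: dict[Parameter, tuple[int, ...]] = {
    Parameter.FASTING_GLUCOSE: (84_521, 9141, 2460, 64, 8, 6),
    Parameter.HEIGHT: (76_815, 10_923, 7752, 608, 82, 20),
    Parameter.WEIGHT: (78_003, 9007, 7311, 1364, 329, 186),
    Parameter.BMI: (80_651, 8482, 6393, 567, 85, 22),
    Parameter.WAIST_CIRCUMFERENCE: (95_812, 349, 39, 0, 0, 0),
    Parameter.GGT: (91_891, 3144, 1067, 77, 12, 9),
    Parameter.SMOKING_STATUS: (96_193, 7, 0, 0, 0, 0),
}

DEFAULT_OCCURRENCE_HISTOGRAMS: dict[Parameter, dict[str, float]] = {
    param: {cls: n / N_REFERENCE for cls, n in zip(OCCURRENCE_CLASSES, counts)}
    for param, counts in _TABLE_COUNTS.items()
}
# Not recorded in structured form at all:
for _absent in (Parameter.WHR, Parameter.ALCOHOL_SERVINGS_PER_WEEK, Parameter.HIP_CIRCUMFERENCE):
    DEFAULT_OCCURRENCE_HISTOGRAMS[_absent] = {"0": 1.0}

# Published per-code diagnosis counts (same N).  Alcohol codes are emitted
# only for latent heavy drinkers, smoking codes only for latent smokers;
# the conditional rates below divide by the latent prevalence so the
# marginal rates match the counts.
ALCOHOL_DX_COUNTS: dict[tuple[str, str], int] = {
    ("ICD-10", "F10.09"): 2158,
    ("ICD-10", "F10.1"): 18_141,
    ("ICD-10", "F10.20"): 3697,
    ("ICD-10", "F10.24"): 3251,
    ("ICD-10", "F10.25"): 3921,
    ("ICD-10", "F10.26"): 3328,
    ("ICD-10", "F10.29"): 3268,
    ("ICD-10", "F10.39"): 1690,
    ("ICPC-2", "P15"): 4494,
    ("ICPC-2", "P16"): 2417,
}
SMOKING_DX_COUNTS: dict[tuple[str, str], int] = {
    ("ICD-10", "Z72.0"): 1102,
    ("ICPC-2", "P17"): 465,
}

# Text snippets by finding family; drawn uniformly when emitted.
SNIPPETS = {
    "alcohol_heavy": (
        "Runsasta alkoholin käyttöä jo vuosien ajan.",
        "Ohjattu katkaisuhoitoon päivystyksestä.",
        "Toistuvia päihtymystiloja, vieroitusoireita aamuisin.",
    ),
    "alcohol_none": (
        "Ei käytä alkoholia.",
        "Potilas ei juo alkoholia lainkaan.",
    ),
    "alcohol_moderate": (
        "Käyttää alkoholia kohtuudella viikonloppuisin.",
    ),
    "smoking_positive": (
        "Tupakoi noin askin päivässä.",
        "Tupakointi jatkuu, motivoitu lopettamaan.",
    ),
    "smoking_negative": (
        "Ei tupakoi.",
        "Tupakoimaton, ei nuuskaa.",
    ),
    "neutral": (
        "Potilas tuli vastaanotolle vuosikontrolliin. Yleistila hyvä.",
        "Verenpaine seurannassa, jatketaan entisellä lääkityksellä.",
        "Polven kipua rasituksessa, ohjattu fysioterapiaan.",
        "Uniongelmia ajoittain, keskusteltu unihygieniasta.",
    ),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults emulate the source data's structure."""

    n_patients: int = 1000
    seed: int = 0
    start_date: dt.date = dt.date(2014, 1, 1)
    end_date: dt.date = dt.date(2022, 6, 30)
    #: Adult age structure: uniform whole-year ages at ``start_date``.
    age_range: tuple[int, int] = (18, 85)
    male_fraction: float = 0.5
    occurrence_histograms: Mapping[Parameter, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_OCCURRENCE_HISTOGRAMS
    )
    # Latent habit prevalences (artifact-chosen plausible adult rates).
    p_heavy_drinker: float = 0.25
    p_smoker: float = 0.20
    p_diabetic: float = 0.08
    #: Per-code emission rates conditional on the latent habit.
    alcohol_dx_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            k: (n / N_REFERENCE) / 0.25 for k, n in ALCOHOL_DX_COUNTS.items()
        }
    )
    smoking_dx_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            k: (n / N_REFERENCE) / 0.20 for k, n in SMOKING_DX_COUNTS.items()
        }
    )
    diabetes_dx_rate: float = 0.5  # E11 emission given latent diabetes
    #: Rates of liver / hepatitis / cancer exclusion diagnoses (per patient).
    exclusion_dx_rates: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("ICD-10", "K74.6"): 0.004,
            ("ICD-10", "K70.3"): 0.003,
            ("ICD-10", "B18.2"): 0.002,
            ("ICD-10", "C22.0"): 0.0005,
        }
    )
    #: Probability that a habit leaves a keyword snippet in the notes.
    text_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "alcohol_heavy": 0.35,
            "alcohol_none": 0.30,
            "alcohol_moderate": 0.05,
            "smoking_positive": 0.30,
            "smoking_negative": 0.30,
        }
    )
    mean_neutral_notes: float = 2.0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.start_date >= self.end_date:
            raise ConfigError("start_date must precede end_date")
        for p in (self.p_heavy_drinker, self.p_smoker, self.p_diabetic, self.male_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        for param, hist in self.occurrence_histograms.items():
            total = sum(hist.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"occurrence histogram for {param.value} sums to {total}, not 1"
                )
        for rates in (self.alcohol_dx_rates, self.smoking_dx_rates, self.exclusion_dx_rates):
            for key, rate in rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ConfigError(f"diagnosis rate for {key} outside [0, 1]: {rate}")


def _random_date(rng: np.random.Generator, start: dt.date, end: dt.date) -> dt.date:
    return start + dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))


def _measurement_value(
    rng: np.random.Generator, parameter: Parameter, sex: Sex, diabetic: bool, smoker: bool
) -> float | bool:
    male = sex is Sex.MALE
    if parameter is Parameter.HEIGHT:
        return float(np.clip(rng.normal(178 if male else 165, 7), 140, 210))
    if parameter is Parameter.WEIGHT:
        return float(np.clip(rng.normal(84 if male else 71, 14), 40, 180))
    if parameter is Parameter.BMI:
        return float(np.clip(rng.normal(27, 4.5), 15, 55))
    if parameter is Parameter.WAIST_CIRCUMFERENCE:
        return float(np.clip(rng.normal(98 if male else 88, 12), 55, 170))
    if parameter is Parameter.HIP_CIRCUMFERENCE:
        return float(np.clip(rng.normal(101 if male else 103, 9), 65, 170))
    if parameter is Parameter.GGT:
        return float(np.exp(rng.normal(np.log(25.0), 0.6)))
    if parameter is Parameter.FASTING_GLUCOSE:
        if diabetic:
            return float(np.clip(rng.normal(8.0, 1.3), 3.0, 25.0))
        return float(np.clip(rng.normal(5.4, 0.5), 3.0, 6.9))
    if parameter is Parameter.SMOKING_STATUS:
        return bool(smoker)
    if parameter is Parameter.WHR:
        return float(np.clip(rng.normal(0.96 if male else 0.84, 0.07), 0.35, 1.95))
    if parameter is Parameter.ALCOHOL_SERVINGS_PER_WEEK:
        return float(rng.integers(0, 30))
    raise DomainError(f"no value model for parameter {parameter}")


def _occurrence_count(rng: np.random.Generator, hist: Mapping[str, float]) -> int:
    classes = list(hist.keys())
    probs = np.array([hist[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    cls = classes[int(rng.choice(len(classes), p=probs))]
    lo, hi = _CLASS_RANGES[cls]
    return int(rng.integers(lo, hi + 1)) if hi > lo else lo


def generate_cohort(config: CohortConfig | None = None) -> list[EventStream]:
    """Generate a reproducible synthetic cohort of event streams.

    Latent habit status (heavy drinker, smoker, diabetic) is drawn first
    and drives structured values, diagnosis emission and text snippets
    coherently, enabling end-to-end recovery tests.  Every returned stream
    passes :func:`clivd.records.validate_stream`.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    width = max(6, len(str(config.n_patients)))
    cohort: list[EventStream] = []
    for i in range(config.n_patients):
        pid = f"SYN-{i + 1:0{width}d}"
        sex = Sex.MALE if rng.random() < config.male_fraction else Sex.FEMALE
        age0 = int(rng.integers(config.age_range[0], config.age_range[1] + 1))
        birth = config.start_date - dt.timedelta(days=int(age0 * 365.25 + rng.integers(0, 365)))
        heavy = rng.random() < config.p_heavy_drinker
        smoker = rng.random() < config.p_smoker
        diabetic = rng.random() < config.p_diabetic

        events: list = []
        for parameter, hist in config.occurrence_histograms.items():
            count = _occurrence_count(rng, hist)
            for _ in range(count):
                events.append(
                    MeasurementEvent(
                        _random_date(rng, config.start_date, config.end_date),
                        parameter,
                        _measurement_value(rng, parameter, sex, diabetic, smoker),
                    )
                )

        def emit_dx(rates: Mapping[tuple[str, str], float], gate: bool = True):
            if not gate:
                return
            for (system, code), rate in rates.items():
                if rng.random() < rate:
                    events.append(
                        DiagnosisEvent(
                            _random_date(rng, config.start_date, config.end_date),
                            CodeSystem(system),
                            code,
                        )
                    )

        emit_dx(config.alcohol_dx_rates, heavy)
        emit_dx(config.smoking_dx_rates, smoker)
        if diabetic and rng.random() < config.diabetes_dx_rate:
            events.append(
                DiagnosisEvent(
                    _random_date(rng, config.start_date, config.end_date),
                    CodeSystem.ICD10,
                    "E11.9",
                )
            )
        emit_dx(config.exclusion_dx_rates)

        def emit_text(key: str, gate: bool):
            if gate and rng.random() < config.text_rates.get(key, 0.0):
                snippets = SNIPPETS[key]
                events.append(
                    TextEvent(
                        _random_date(rng, config.start_date, config.end_date),
                        snippets[int(rng.integers(0, len(snippets)))],
                    )
                )

        emit_text("alcohol_heavy", heavy)
        emit_text("alcohol_none", not heavy)
        emit_text("alcohol_moderate", not heavy)
        emit_text("smoking_positive", smoker)
        emit_text("smoking_negative", not smoker)
        for _ in range(rng.poisson(config.mean_neutral_notes)):
            snippets = SNIPPETS["neutral"]
            events.append(
                TextEvent(
                    _random_date(rng, config.start_date, config.end_date),
                    snippets[int(rng.integers(0, len(snippets)))],
                )
            )

        cohort.append(EventStream(Patient(pid, sex, birth), tuple(events)))
    return cohort


def occurrence_histogram(cohort: list[EventStream], parameter: Parameter) -> dict[str, int]:
    """Count patients by occurrence class of one parameter over history.

    Classes partition the cohort; counts sum to the cohort size.
    """
    if not isinstance(parameter, Parameter):
        raise DomainError(f"unknown parameter {parameter!r}")
    counts = {cls: 0 for cls in OCCURRENCE_CLASSES}
    for stream in cohort:
        n = len(stream.measurements(parameter))
        for cls, (lo, hi) in _CLASS_RANGES.items():
            if cls == ">15":
                if n > 15:
                    counts[cls] += 1
                    break
            elif lo <= n <= hi:
                counts[cls] += 1
                break
    return counts
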