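"""The CLivD risk function, exclusion screening, default substitution and
risk categorization.

The CLivD score predicts an individual's 10-year risk of severe chronic
liver disease from sex, age, smoking, weekly alcohol servings, diabetes and
waist-hip ratio (WHR); the *lab* variant additionally uses the GGT
laboratory value, the *nonlab* variant is used when GGT is unavailable.
Risk is a Cox-type transform ``1 - S0 ** exp(lp)`` of a linear predictor in
centered covariates, with coefficients loaded from a transcription config
file (the file shipped with the package is a labelled-synthetic
calibration; see its provenance note).

Missing inputs are never imputed to a point value.  Instead each missing
parameter is substituted by its extreme defaults — WHR (0.7, 1.3), smoking
(false, true), alcohol (0, 49 servings/week), diabetes (false, true) — and
the score is evaluated at both ends, yielding a (minimum risk, maximum
risk) interval whose width measures the precision of the assessment.
Categorization against the 5%/10% cutoffs then maps intervals to
low / moderate / high / not-specified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, ConsistencyError, DomainError
from .records import CodeSystem, Parameter, Sex
from .timeline import ParameterState, ParameterValue, Source

__all__ = [
    "Variant",
    "RiskCoefficients",
    "RiskModelConfig",
    "load_model_config",
    "InputVector",
    "InputInterval",
    "RiskInterval",
    "RiskCategory",
    "ExclusionReason",
    "ExclusionResult",
    "screen_exclusions",
    "derive_diabetes",
    "resolve_inputs",
    "clivd_score",
    "risk_interval",
    "categorize",
    "DEFAULTS",
]


class Variant(str, Enum):
    LAB = "lab"
    NONLAB = "nonlab"


_REQUIRED_COEFFS = {
    Variant.NONLAB: (
        "male",
        "age_per_year",
        "smoker",
        "alcohol_per_weekly_serving",
        "whr_per_unit",
        "diabetes",
    ),
    Variant.LAB: (
        "male",
        "age_per_year",
        "smoker",
        "alcohol_per_weekly_serving",
        "whr_per_unit",
        "diabetes",
        "log_ggt",
    ),
}


@dataclass(frozen=True)
class RiskCoefficients:
    """One variant's transcribed coefficient set and baseline survival."""

    variant: Variant
    baseline_survival_10y: float
    coefficients: Mapping[str, float]
    centering: Mapping[str, float]
    provenance: str = ""

    def __post_init__(self):
        for name in _REQUIRED_COEFFS[self.variant]:
            if name not in self.coefficients:
                raise ConfigError(f"{self.variant.value} model missing coefficient {name!r}")
        for name, value in {**self.coefficients, **self.centering}.items():
            if not math.isfinite(value):
                raise ConfigError(f"coefficient {name!r} is not finite")
        if not 0.0 < self.baseline_survival_10y < 1.0:
            raise ConfigError("baseline_survival_10y must lie in (0, 1)")


# Extreme substitution values for missing inputs: (minimum-risk end,
# maximum-risk end).  Age is bounded by the eligible window and is in
# practice always available.
DEFAULTS: dict[str, tuple] = {
    "whr": (0.7, 1.3),
    "smoker": (False, True),
    "alcohol_servings_per_week": (0.0, 49.0),
    "diabetes": (False, True),
    "age": (40, 70),
}


@dataclass(frozen=True)
class RiskModelConfig:
    models: Mapping[Variant, RiskCoefficients]
    cutoffs: tuple[float, float] = (0.05, 0.10)
    age_window: tuple[int, int] = (40, 70)
    #: ICD-10 / ICPC-2 prefixes treated as a diabetes diagnosis.
    diabetes_code_prefixes: tuple[tuple[str, str], ...] = (
        ("ICD-10", "E10"),
        ("ICD-10", "E11"),
        ("ICD-10", "E12"),
        ("ICD-10", "E13"),
        ("ICD-10", "E14"),
        ("ICPC-2", "T89"),
        ("ICPC-2", "T90"),
    )
    #: "text_confirmed": F10.2x flags abstainer exclusion only with
    #: co-occurring abstinence text evidence; "code_only": the code suffices.
    abstainer_mode: str = "text_confirmed"
    #: Default reading: a missing glucose/diagnosis means no diabetes.  Set
    #: True to fall back to the (False, True) default interval instead.
    missing_diabetes_unknown: bool = False

    def __post_init__(self):
        if self.cutoffs[0] > self.cutoffs[1]:
            raise ConfigError("low cutoff must not exceed high cutoff")
        if self.abstainer_mode not in ("text_confirmed", "code_only"):
            raise ConfigError(f"unknown abstainer_mode {self.abstainer_mode!r}")


def load_model_config(path: str | Path | None = None) -> RiskModelConfig:
    """Load coefficients and screening settings from a YAML transcription file.

    With no path, the packaged labelled-synthetic calibration is used.
    """
    if path is None:
        text = (
            resources.files("clivd.data")
            .joinpath("clivd_coefficients_synthetic.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    try:
        provenance = raw.get("provenance", "")
        models = {}
        for key, block in raw["models"].items():
            variant = Variant(key)
            models[variant] = RiskCoefficients(
                variant=variant,
                baseline_survival_10y=float(block["baseline_survival_10y"]),
                coefficients={k: float(v) for k, v in block["coefficients"].items()},
                centering={k: float(v) for k, v in block.get("centering", {}).items()},
                provenance=provenance,
            )
        cutoffs = (float(raw["cutoffs"]["low"]), float(raw["cutoffs"]["high"]))
        window = (int(raw["age_window"]["min"]), int(raw["age_window"]["max"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"bad coefficient file: {exc!r}") from None
    if Variant.NONLAB not in models:
        raise ConfigError("coefficient file must define the nonlab model")
    return RiskModelConfig(models=models, cutoffs=cutoffs, age_window=window)


# ---------------------------------------------------------------------------
# Exclusion screening


class ExclusionReason(str, Enum):
    AGE_OUT_OF_RANGE = "age_out_of_range"
    LIVER_DISEASE_DX = "liver_disease_dx"
    VIRAL_HEPATITIS_DX = "viral_hepatitis_dx"
    ALCOHOL_ABSTAINER_PRIOR_USE = "alcohol_abstainer_prior_use"


@dataclass(frozen=True)
class ExclusionResult:
    excluded: bool
    reasons: frozenset[ExclusionReason]


_LIVER_PREFIXES = tuple(f"K7{i}" for i in range(8))  # K70..K77 families


def screen_exclusions(
    state: ParameterState,
    config: RiskModelConfig | None = None,
    *,
    abstinence_evidence: bool = False,
) -> ExclusionResult:
    """Apply the risk model's exclusion criteria at the state's query date.

    Criteria: age outside the eligible window; any liver disease diagnosis
    (ICD-10 K70-K77 families or C22.0); chronic viral hepatitis (B18.x);
    and the current-abstainer-with-prior-use criterion flagged from alcohol
    dependence codes (F10.2x), by default only when abstinence text
    evidence co-occurs (``abstainer_mode='text_confirmed'``).
    """
    config = config or _default_config()
    reasons: set[ExclusionReason] = set()
    lo, hi = config.age_window
    if not lo <= state.age <= hi:
        reasons.add(ExclusionReason.AGE_OUT_OF_RANGE)
    f102 = False
    for system, code in state.active_diagnoses:
        if system == CodeSystem.ICD10.value:
            if code.startswith(_LIVER_PREFIXES) or code == "C22.0":
                reasons.add(ExclusionReason.LIVER_DISEASE_DX)
            if code.startswith("B18"):
                reasons.add(ExclusionReason.VIRAL_HEPATITIS_DX)
            if code.startswith("F10.2"):
                f102 = True
    if f102 and (config.abstainer_mode == "code_only" or abstinence_evidence):
        reasons.add(ExclusionReason.ALCOHOL_ABSTAINER_PRIOR_USE)
    return ExclusionResult(excluded=bool(reasons), reasons=frozenset(reasons))


GLUCOSE_DIABETES_THRESHOLD = 7.0  # mmol/L, diagnostic fasting-glucose cutoff


def derive_diabetes(state: ParameterState, config: RiskModelConfig | None = None) -> bool | None:
    """Diabetes status from diagnoses or fasting glucose.

    True with an active diabetes diagnosis or a valid fasting glucose
    >= 7 mmol/L; False with a sub-threshold glucose and no diagnosis.  With
    no evidence at all the default reading is False (a missing measurement
    is taken to mean no diabetes); configure ``missing_diabetes_unknown``
    to get ``None`` (unknown) instead.
    """
    config = config or _default_config()
    for system, code in state.active_diagnoses:
        for psys, prefix in config.diabetes_code_prefixes:
            if system == psys and code.startswith(prefix):
                return True
    glucose = state.get(Parameter.FASTING_GLUCOSE)
    if glucose.source is not Source.MISSING:
        return float(glucose.value) >= GLUCOSE_DIABETES_THRESHOLD
    return None if config.missing_diabetes_unknown else False


# ---------------------------------------------------------------------------
# Input resolution


@dataclass(frozen=True)
class InputVector:
    """A complete input vector for one end of the risk interval."""

    sex: Sex
    age: int
    smoker: bool
    alcohol_servings_per_week: float
    diabetes: bool
    whr: float
    ggt: float | None = None
    variant: Variant = Variant.NONLAB


@dataclass(frozen=True)
class InputInterval:
    """Minimum- and maximum-risk input vectors after default substitution.

    ``substituted`` names every parameter whose two ends differ, whether
    filled from the extreme defaults or bounded by category-valued
    evidence; all other parameters are equal in both vectors.
    """

    min_inputs: InputVector
    max_inputs: InputVector
    substituted: frozenset[str]

    def __post_init__(self):
        lo, hi = self.min_inputs, self.max_inputs
        checks = [
            ("age", lo.age, hi.age),
            ("smoker", lo.smoker, hi.smoker),
            ("alcohol_servings_per_week", lo.alcohol_servings_per_week, hi.alcohol_servings_per_week),
            ("diabetes", lo.diabetes, hi.diabetes),
            ("whr", lo.whr, hi.whr),
        ]
        for name, a, b in checks:
            if a > b:
                raise ConsistencyError(f"min input {name} exceeds max input ({a} > {b})")
            if name not in self.substituted and a != b:
                raise ConsistencyError(f"non-substituted input {name} differs across ends")


def _bounds(pv: ParameterValue) -> tuple[float, float] | None:
    if pv.source is Source.MISSING:
        return None
    if isinstance(pv.value, tuple):
        return (float(pv.value[0]), float(pv.value[1]))
    return (float(pv.value), float(pv.value))


def resolve_inputs(
    state: ParameterState,
    config: RiskModelConfig | None = None,
) -> InputInterval:
    """Build the (minimum, maximum) input pair from a resolved state.

    Observed or derived parameters enter both vectors; each missing
    parameter is substituted by its extreme defaults; category-valued
    evidence (alcohol categories, WHR bins) contributes its own bounds.
    Missing GGT switches both ends to the nonlab variant.
    """
    config = config or _default_config()
    lo_age, hi_age = config.age_window
    if not lo_age <= state.age <= hi_age:
        raise DomainError(
            f"age {state.age} outside eligible window [{lo_age}, {hi_age}]; "
            "screen_exclusions must run first"
        )

    substituted: set[str] = set()

    def span(pv: ParameterValue, name: str, default: tuple[float, float]) -> tuple[float, float]:
        b = _bounds(pv)
        if b is None:
            substituted.add(name)
            return default
        if b[0] != b[1]:
            substituted.add(name)
        return b

    whr_lo, whr_hi = span(state.get(Parameter.WHR), "whr", DEFAULTS["whr"])
    alc_lo, alc_hi = span(
        state.get(Parameter.ALCOHOL_SERVINGS_PER_WEEK),
        "alcohol_servings_per_week",
        DEFAULTS["alcohol_servings_per_week"],
    )

    smoking = state.get(Parameter.SMOKING_STATUS)
    if smoking.source is Source.MISSING:
        substituted.add("smoker")
        smoker_lo, smoker_hi = DEFAULTS["smoker"]
    else:
        smoker_lo = smoker_hi = bool(smoking.value)

    diabetes = derive_diabetes(state, config)
    if diabetes is None:
        substituted.add("diabetes")
        diabetes_lo, diabetes_hi = DEFAULTS["diabetes"]
    else:
        diabetes_lo = diabetes_hi = diabetes

    ggt = state.get(Parameter.GGT)
    if ggt.source is Source.MISSING or Variant.LAB not in config.models:
        variant, ggt_value = Variant.NONLAB, None
    else:
        variant, ggt_value = Variant.LAB, float(ggt.value)

    return InputInterval(
        min_inputs=InputVector(
            sex=state.sex, age=state.age, smoker=smoker_lo,
            alcohol_servings_per_week=alc_lo, diabetes=diabetes_lo,
            whr=whr_lo, ggt=ggt_value, variant=variant,
        ),
        max_inputs=InputVector(
            sex=state.sex, age=state.age, smoker=smoker_hi,
            alcohol_servings_per_week=alc_hi, diabetes=diabetes_hi,
            whr=whr_hi, ggt=ggt_value, variant=variant,
        ),
        substituted=frozenset(substituted),
    )


# ---------------------------------------------------------------------------
# Scoring and categorization


def clivd_score(inputs: InputVector, coefficients: RiskCoefficients) -> float:
    """10-year risk for one complete input vector: ``1 - S0 ** exp(lp)``.

    The linear predictor sums coefficient-weighted, center-shifted
    covariates; the lab variant adds a log-GGT term, the nonlab variant
    ignores GGT entirely.  Deterministic; returns a probability in [0, 1].
    """
    if inputs.variant is not coefficients.variant:
        raise ConfigError(
            f"input vector is for the {inputs.variant.value} variant but coefficients "
            f"are for {coefficients.variant.value}"
        )
    c = coefficients.coefficients
    center = coefficients.centering
    lp = (
        c["male"] * (1.0 if inputs.sex is Sex.MALE else 0.0)
        + c["age_per_year"] * (inputs.age - center.get("age_years", 0.0))
        + c["smoker"] * (1.0 if inputs.smoker else 0.0)
        + c["alcohol_per_weekly_serving"] * inputs.alcohol_servings_per_week
        + c["whr_per_unit"] * (inputs.whr - center.get("whr", 0.0))
        + c["diabetes"] * (1.0 if inputs.diabetes else 0.0)
    )
    if coefficients.variant is Variant.LAB:
        if inputs.ggt is None:
            raise DomainError("lab variant requires a GGT value")
        if inputs.ggt <= 0:
            raise DomainError("GGT must be positive")
        lp += c["log_ggt"] * (math.log(inputs.ggt) - center.get("log_ggt", 0.0))
    risk = 1.0 - coefficients.baseline_survival_10y ** math.exp(lp)
    return min(max(risk, 0.0), 1.0)


@dataclass(frozen=True)
class RiskInterval:
    """(minimum, maximum) 10-year risk; the width measures precision."""

    risk_min: float
    risk_max: float

    def __post_init__(self):
        if not (0.0 <= self.risk_min <= self.risk_max <= 1.0):
            raise ConsistencyError(
                f"invalid risk interval ({self.risk_min}, {self.risk_max})"
            )

    @property
    def width(self) -> float:
        return self.risk_max - self.risk_min


def risk_interval(interval: InputInterval, config: RiskModelConfig) -> RiskInterval:
    """Score both ends of an input interval.

    Raises :class:`ConsistencyError` if the maximum end scores below the
    minimum end — that would indicate a non-monotone coefficient
    transcription, not a data problem.
    """
    coeffs = config.models[interval.min_inputs.variant]
    lo = clivd_score(interval.min_inputs, coeffs)
    hi = clivd_score(interval.max_inputs, coeffs)
    if lo > hi + 1e-12:
        raise ConsistencyError(
            f"risk at the minimum end ({lo}) exceeds the maximum end ({hi}); "
            "check the coefficient transcription for monotonicity"
        )
    return RiskInterval(risk_min=min(lo, hi), risk_max=hi)


class RiskCategory(str, Enum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    NOT_SPECIFIED = "not_specified"


def categorize(
    interval: RiskInterval, cutoffs: tuple[float, float] = (0.05, 0.10)
) -> RiskCategory:
    """Map a risk interval to a category against the (low, high) cutoffs.

    Decision order: *high* if the minimum risk already reaches the high
    cutoff; else *low* if even the maximum risk stays under the low cutoff;
    else *moderate* if the minimum risk exceeds the low cutoff; otherwise
    the interval straddles the cutoffs and the category is *not specified*.
    Total and single-valued for every 0 <= min <= max <= 1.
    """
    low_cut, high_cut = cutoffs
    if low_cut > high_cut:
        raise ConfigError("low cutoff must not exceed high cutoff")
    if interval.risk_min >= high_cut:
        return RiskCategory.HIGH
    if interval.risk_max < low_cut:
        return RiskCategory.LOW
    if interval.risk_min > low_cut:
        return RiskCategory.MODERATE
    return RiskCategory.NOT_SPECIFIED


_DEFAULT_CONFIG: RiskModelConfig | None = None


def _default_config() -> RiskModelConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = load_model_config()
    return _DEFAULT_CONFIG
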