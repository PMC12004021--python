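"""Diagnosis-code and free-text enrichment of risk-model inputs.

Structured records rarely contain smoking status, alcohol use or WHR, so
this module recovers *bounded* evidence from two auxiliary sources:

* diagnosis codes — hazardous-drinking codes (F10.x families, P15/P16)
  floor the weekly alcohol servings at the THL risk limits (23 for men,
  12 for women, ceiling 49); tobacco codes (Z72.0, P17) pin smoking to
  true, which is exact for the risk model (it ignores quantity);
* Finnish clinical narrative — a regex keyword search converts phrases
  into smoking status or alcohol-use categories, each category carrying
  (min, max) weekly-serving bounds.

Evidence sources merge with precedence structured > text > diagnosis:
professionally recorded exact values beat narrative findings, which beat
coarse code approximations.  Text findings age like measurements (habits
change), diagnoses accumulate.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError
from .records import Parameter, Sex, TextEvent
from .timeline import LifecyclePolicy, ParameterState, ParameterValue, Source

__all__ = [
    "AlcoholCategoryTable",
    "CodeMapping",
    "KeywordTable",
    "TextFinding",
    "FindingKind",
    "DiagnosisEvidence",
    "map_diagnoses",
    "extract_text_findings",
    "alcohol_category_to_bounds",
    "merge_evidence",
    "load_code_mapping",
    "load_keyword_table",
    "load_alcohol_categories",
]

#: THL hazardous-drinking floors (weekly servings) and the substitution ceiling.
HEAVY_FLOOR = {Sex.MALE: 23.0, Sex.FEMALE: 12.0}
SERVINGS_CEILING = 49.0


def _read_data(name: str, path: str | Path | None) -> dict:
    if path is None:
        text = resources.files("clivd.data").joinpath(name).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Alcohol categories


@dataclass(frozen=True)
class AlcoholCategoryTable:
    """Named alcohol-use categories with sex-specific weekly-serving bounds."""

    categories: Mapping[str, Mapping[Sex, tuple[float, float]]]

    def __post_init__(self):
        for name, by_sex in self.categories.items():
            for sex, (lo, hi) in by_sex.items():
                if not 0 <= lo <= hi <= SERVINGS_CEILING:
                    raise ConfigError(
                        f"category {name!r}/{sex.value}: bounds ({lo}, {hi}) must satisfy "
                        f"0 <= min <= max <= {SERVINGS_CEILING}"
                    )

    def bounds(self, category: str, sex: Sex) -> tuple[float, float]:
        if category not in self.categories:
            raise ConfigError(f"unknown alcohol category {category!r}")
        return self.categories[category][sex]


def load_alcohol_categories(path: str | Path | None = None) -> AlcoholCategoryTable:
    raw = _read_data("alcohol_categories.yaml", path)
    categories = {
        name: {Sex(sex): (float(lo), float(hi)) for sex, (lo, hi) in by_sex.items()}
        for name, by_sex in raw["categories"].items()
    }
    return AlcoholCategoryTable(categories)


def alcohol_category_to_bounds(
    category: str, sex: Sex, table: AlcoholCategoryTable | None = None
) -> tuple[float, float]:
    """Weekly-serving (min, max) for a named category; heavy floors at the
    THL limits (23 men / 12 women) with the 49-serving ceiling."""
    table = table or _default_categories()
    return table.bounds(category, sex)


# ---------------------------------------------------------------------------
# Diagnosis mapping


class Effect(str, Enum):
    SMOKER_TRUE = "smoker_true"
    ALCOHOL_HEAVY = "alcohol_heavy"
    ABSTAINER_FLAG = "abstainer_flag"


@dataclass(frozen=True)
class CodeMapping:
    """(system, code-pattern) -> effect; a trailing 'X' makes a family prefix."""

    entries: tuple[tuple[str, str, Effect], ...]

    def __post_init__(self):
        seen: dict[tuple[str, str], Effect] = {}
        for system, pattern, effect in self.entries:
            key = (system, pattern)
            if seen.get(key, effect) is not effect:
                raise ConfigError(f"pattern {key} maps to two effects")
            seen[key] = effect

    def effects_for(self, system: str, code: str) -> set[Effect]:
        out = set()
        for psys, pattern, effect in self.entries:
            if psys != system:
                continue
            if pattern.endswith("X"):
                if code.startswith(pattern[:-1]):
                    out.add(effect)
            elif code == pattern:
                out.add(effect)
        return out


def load_code_mapping(path: str | Path | None = None) -> CodeMapping:
    raw = _read_data("code_mapping.yaml", path)
    entries = tuple(
        (e["system"], e["code"], Effect(e["effect"])) for e in raw["entries"]
    )
    return CodeMapping(entries)


@dataclass(frozen=True)
class DiagnosisEvidence:
    """Partial evidence recovered from active diagnosis codes."""

    smoker: bool | None = None
    smoker_date: dt.date | None = None
    alcohol_bounds: tuple[float, float] | None = None
    alcohol_date: dt.date | None = None


def map_diagnoses(
    diagnoses: Iterable[tuple[str, str]],
    sex: Sex,
    mapping: CodeMapping | None = None,
    dates: Mapping[tuple[str, str], dt.date] | None = None,
) -> DiagnosisEvidence:
    """Convert an active diagnosis set into smoking/alcohol evidence.

    Heavy-alcohol codes floor weekly servings at 23 (men) / 12 (women)
    with the substitution ceiling 49; tobacco codes set smoking true;
    unmapped codes contribute nothing.
    """
    mapping = mapping or _default_mapping()
    dates = dates or {}
    smoker: bool | None = None
    smoker_date: dt.date | None = None
    alcohol: tuple[float, float] | None = None
    alcohol_date: dt.date | None = None
    for system, code in diagnoses:
        effects = mapping.effects_for(system, code)
        when = dates.get((system, code))
        if Effect.SMOKER_TRUE in effects:
            smoker = True
            if when and (smoker_date is None or when > smoker_date):
                smoker_date = when
        if Effect.ALCOHOL_HEAVY in effects:
            alcohol = (HEAVY_FLOOR[sex], SERVINGS_CEILING)
            if when and (alcohol_date is None or when > alcohol_date):
                alcohol_date = when
    return DiagnosisEvidence(smoker, smoker_date, alcohol, alcohol_date)


# ---------------------------------------------------------------------------
# Free-text findings


class FindingKind(str, Enum):
    SMOKING_POSITIVE = "smoking_positive"
    SMOKING_NEGATIVE = "smoking_negative"
    ALCOHOL_CATEGORY = "alcohol_category"


@dataclass(frozen=True)
class TextFinding:
    date: dt.date
    kind: FindingKind
    category: str | None
    matched_span: str

    def __post_init__(self):
        if self.kind is FindingKind.ALCOHOL_CATEGORY and not self.category:
            raise ConfigError("alcohol_category finding requires a category name")


@dataclass(frozen=True)
class KeywordPattern:
    kind: FindingKind
    regex: re.Pattern
    category: str | None = None
    negation: bool = False


@dataclass(frozen=True)
class KeywordTable:
    patterns: tuple[KeywordPattern, ...]


def load_keyword_table(path: str | Path | None = None) -> KeywordTable:
    raw = _read_data("keywords.yaml", path)
    patterns = []
    for entry in raw["patterns"]:
        try:
            compiled = re.compile(entry["regex"], re.IGNORECASE)
        except re.error as exc:
            raise ConfigError(f"invalid keyword pattern {entry['regex']!r}: {exc}") from None
        patterns.append(
            KeywordPattern(
                kind=FindingKind(entry["kind"]),
                regex=compiled,
                category=entry.get("category"),
                negation=bool(entry.get("negation", False)),
            )
        )
    return KeywordTable(tuple(patterns))


def extract_text_findings(
    event: TextEvent, table: KeywordTable | None = None
) -> list[TextFinding]:
    """Case-insensitive keyword search over one narrative; pure function.

    Negation patterns ("ei ... alkohol", "ei tupakoi") win over positive
    stems they overlap: a positive match whose span intersects a negation
    match is dropped, and the negation itself converts to the abstinent /
    non-smoking finding it carries.
    """
    table = table or _default_keywords()
    raw: list[tuple[KeywordPattern, tuple[int, int], str]] = []
    for pattern in table.patterns:
        for m in pattern.regex.finditer(event.text):
            raw.append((pattern, m.span(), m.group(0)))

    negation_spans = [span for pattern, span, _ in raw if pattern.negation]

    def suppressed(span: tuple[int, int]) -> bool:
        return any(span[0] < n[1] and n[0] < span[1] for n in negation_spans)

    found: list[tuple[tuple[int, int], TextFinding]] = []
    for pattern, span, text in raw:
        if not pattern.negation and suppressed(span):
            continue
        found.append((span, TextFinding(event.date, pattern.kind, pattern.category, text)))
    found.sort(key=lambda item: item[0])  # deterministic: by position in text
    return [finding for _, finding in found]


# ---------------------------------------------------------------------------
# Evidence merge


def merge_evidence(
    state: ParameterState,
    dx: DiagnosisEvidence | None = None,
    findings: Sequence[TextFinding] = (),
    policy: LifecyclePolicy | None = None,
    category_table: AlcoholCategoryTable | None = None,
) -> ParameterState:
    """Merge structured, text and diagnosis evidence into an enriched state.

    Precedence structured > text > diagnosis for smoking and alcohol;
    within the text source the most recent valid finding wins (same-date
    ties: last in sequence).  Text findings obey the measurement lifecycle:
    a finding is valid at the query date iff a measurement on its date
    would be.  Returns a new state; never mutates input.
    """
    policy = policy or LifecyclePolicy()
    table = category_table or _default_categories()
    values = dict(state.values)

    def finding_valid(f: TextFinding) -> bool:
        if f.date > state.query_date + policy.lookback:
            return False
        lifetime = policy.measurement_lifetime
        if lifetime is None:
            return True
        return state.query_date < f.date + lifetime

    valid = [f for f in findings if finding_valid(f)]

    def latest(kinds: set[FindingKind]) -> TextFinding | None:
        best = None
        for f in valid:
            if f.kind in kinds and (best is None or f.date >= best.date):
                best = f
        return best

    # Under the infinite lifecycle "most recent wins" must consider only
    # findings not superseded by a later finding of the same family.
    if not state.present(Parameter.SMOKING_STATUS):
        f = latest({FindingKind.SMOKING_POSITIVE, FindingKind.SMOKING_NEGATIVE})
        if f is not None:
            values[Parameter.SMOKING_STATUS] = ParameterValue(
                f.kind is FindingKind.SMOKING_POSITIVE, Source.TEXT, f.date
            )
        elif dx is not None and dx.smoker is not None:
            values[Parameter.SMOKING_STATUS] = ParameterValue(
                dx.smoker, Source.DIAGNOSIS, dx.smoker_date
            )

    if not state.present(Parameter.ALCOHOL_SERVINGS_PER_WEEK):
        f = latest({FindingKind.ALCOHOL_CATEGORY})
        if f is not None:
            bounds = table.bounds(f.category, state.sex)
            values[Parameter.ALCOHOL_SERVINGS_PER_WEEK] = ParameterValue(
                bounds, Source.TEXT, f.date
            )
        elif dx is not None and dx.alcohol_bounds is not None:
            values[Parameter.ALCOHOL_SERVINGS_PER_WEEK] = ParameterValue(
                dx.alcohol_bounds, Source.DIAGNOSIS, dx.alcohol_date
            )

    return ParameterState(
        query_date=state.query_date,
        age=state.age,
        sex=state.sex,
        values=values,
        active_diagnoses=state.active_diagnoses,
        diagnosis_dates=state.diagnosis_dates,
    )


# ---------------------------------------------------------------------------
# Default singletons (loaded lazily from packaged config)

_MAPPING: CodeMapping | None = None
_KEYWORDS: KeywordTable | None = None
_CATEGORIES: AlcoholCategoryTable | None = None


def _default_mapping() -> CodeMapping:
    global _MAPPING
    if _MAPPING is None:
        _MAPPING = load_code_mapping()
    return _MAPPING


def _default_keywords() -> KeywordTable:
    global _KEYWORDS
    if _KEYWORDS is None:
        _KEYWORDS = load_keyword_table()
    return _KEYWORDS


def _default_categories() -> AlcoholCategoryTable:
    global _CATEGORIES
    if _CATEGORIES is None:
        _CATEGORIES = load_alcohol_categories()
    return _CATEGORIES
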