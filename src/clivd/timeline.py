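"""Parameter-lifecycle resolution: which inputs are valid at a query date.

Longitudinal records are measured at scattered dates, while the risk model
expects a cross-sectional input vector, so every measurement is given a
validity window.  Two presets mirror common practice: ``one_year`` (a
measurement is valid for one year after it is taken) and ``infinite`` (it
stays valid until the next measurement of the same parameter, or to the end
of history).  Diagnoses accumulate with infinite validity under both
presets; habits inferred from text are handled upstream but obey the
measurement lifetime (see :mod:`clivd.enrichment`).

Validity is forward-only by default: a measurement never informs dates
before it was taken.  A ``lookback`` duration can relax this for users who
want symmetric windows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from .errors import ConfigError, DomainError
from .records import (
    DiagnosisEvent,
    EventStream,
    MeasurementEvent,
    Parameter,
    Sex,
)

__all__ = [
    "LifecyclePolicy",
    "Source",
    "ParameterValue",
    "ParameterState",
    "state_at",
    "annual_grid",
    "age_at",
    "POLICY_PRESETS",
]

#: Adults only: no state may be resolved before the 18th birthday.
MIN_AGE = 18

ONE_YEAR = dt.timedelta(days=365)


@dataclass(frozen=True)
class LifecyclePolicy:
    """Validity windows for measurements and diagnoses.

    ``None`` means infinite validity (until superseded by the next same-
    parameter measurement; diagnoses are never superseded).
    """

    measurement_lifetime: dt.timedelta | None = None
    diagnosis_lifetime: dt.timedelta | None = None
    lookback: dt.timedelta = dt.timedelta(0)
    overrides: Mapping[Parameter, dt.timedelta | None] = field(default_factory=dict)

    def __post_init__(self):
        for name, value in [
            ("measurement_lifetime", self.measurement_lifetime),
            ("diagnosis_lifetime", self.diagnosis_lifetime),
            *((f"override[{p.value}]", v) for p, v in self.overrides.items()),
        ]:
            if value is not None and value <= dt.timedelta(0):
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if self.lookback < dt.timedelta(0):
            raise ConfigError("lookback must be non-negative")

    def lifetime_for(self, parameter: Parameter) -> dt.timedelta | None:
        return self.overrides.get(parameter, self.measurement_lifetime)


POLICY_PRESETS: dict[str, LifecyclePolicy] = {
    "one_year": LifecyclePolicy(measurement_lifetime=ONE_YEAR),
    "infinite": LifecyclePolicy(measurement_lifetime=None),
}


class Source(str, Enum):
    STRUCTURED = "structured"
    DIAGNOSIS = "diagnosis"
    TEXT = "text"
    SIMULATED = "simulated"
    MISSING = "missing"


@dataclass(frozen=True)
class ParameterValue:
    """A resolved input: value, provenance, and the date it was observed.

    ``value`` is a float/bool for exact observations, or a ``(low, high)``
    tuple for category-valued evidence (alcohol-use categories, WHR bins)
    that bounds the quantity without pinning it.
    """

    value: float | bool | tuple[float, float]
    source: Source
    source_date: dt.date | None


MISSING = ParameterValue(value=float("nan"), source=Source.MISSING, source_date=None)


@dataclass(frozen=True)
class ParameterState:
    """All risk-model inputs resolved at one query date for one patient."""

    query_date: dt.date
    age: int
    sex: Sex
    values: Mapping[Parameter, ParameterValue]
    active_diagnoses: frozenset[tuple[str, str]]  # (system value, code)
    diagnosis_dates: Mapping[tuple[str, str], dt.date] = field(default_factory=dict)

    def get(self, parameter: Parameter) -> ParameterValue:
        return self.values.get(parameter, MISSING)

    def present(self, parameter: Parameter) -> bool:
        return self.get(parameter).source is not Source.MISSING


def age_at(birth_date: dt.date, date: dt.date) -> int:
    """Whole years elapsed since birth."""
    years = date.year - birth_date.year
    if (date.month, date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _measurement_valid(
    event: MeasurementEvent, next_date: dt.date | None, date: dt.date, policy: LifecyclePolicy
) -> bool:
    start = event.date - policy.lookback
    if date < start:
        return False
    lifetime = policy.lifetime_for(event.parameter)
    if lifetime is None:
        # Valid until superseded by the next same-parameter measurement.
        return next_date is None or date < next_date
    return date < event.date + lifetime


def state_at(stream: EventStream, date: dt.date, policy: LifecyclePolicy) -> ParameterState:
    """Resolve the inputs valid at ``date`` under ``policy``.

    For each parameter the most recent measurement whose validity window
    covers ``date`` wins; same-date ties resolve to the last record in file
    order.  Diagnoses dated on or before ``date`` accumulate (subject to
    ``diagnosis_lifetime``, infinite by default).

    Raises :class:`DomainError` before the patient's 18th birthday.
    """
    age = age_at(stream.patient.birth_date, date)
    if age < MIN_AGE:
        raise DomainError(
            f"query date {date.isoformat()} precedes patient "
            f"{stream.patient.patient_id!r}'s 18th birthday"
        )

    by_param: dict[Parameter, list[MeasurementEvent]] = {}
    for event in stream.events:
        if isinstance(event, MeasurementEvent):
            by_param.setdefault(event.parameter, []).append(event)

    values: dict[Parameter, ParameterValue] = {}
    for parameter, events in by_param.items():
        chosen: MeasurementEvent | None = None
        for i, event in enumerate(events):
            next_date = next((e.date for e in events[i + 1 :] if e.date > event.date), None)
            if _measurement_valid(event, next_date, date, policy):
                chosen = event  # keep scanning: later (and same-date later) events win
        if chosen is not None:
            source = Source.SIMULATED if chosen.source == "simulated" else Source.STRUCTURED
            values[parameter] = ParameterValue(chosen.value, source, chosen.date)

    active: set[tuple[str, str]] = set()
    dx_dates: dict[tuple[str, str], dt.date] = {}
    for event in stream.events:
        if isinstance(event, DiagnosisEvent) and event.date <= date:
            if (
                policy.diagnosis_lifetime is not None
                and date >= event.date + policy.diagnosis_lifetime
            ):
                continue
            key = (event.system.value, event.code)
            active.add(key)
            dx_dates[key] = max(dx_dates.get(key, event.date), event.date)

    return ParameterState(
        query_date=date,
        age=age,
        sex=stream.patient.sex,
        values=values,
        active_diagnoses=frozenset(active),
        diagnosis_dates=dx_dates,
    )


def annual_grid(
    stream: EventStream,
    years: range | list[int],
    policy: LifecyclePolicy,
) -> list[tuple[dt.date, ParameterState]]:
    """One resolved state per year, evaluated at Dec 31 of each year."""
    for year in years:
        if not 2000 <= year <= 2100:
            raise DomainError(f"grid year {year} outside supported range 2000-2100")
    return [
        (d, state_at(stream, d, policy))
        for year in years
        for d in [dt.date(year, 12, 31)]
    ]
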