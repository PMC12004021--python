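"""Patient event data model and the line-delimited record format.

A cohort is stored as JSON Lines: one JSON object per line, either a
``patient`` record (demographics) or an event record (``measurement``,
``diagnosis`` or ``text``).  The format is the artifact's stand-in for
parsed national-repository document content: streamable, diffable and
trivially generated.  See ``docs/format.md`` for the full schema.

Measurement parameters follow the risk model's vocabulary: fasting
glucose (mmol/L), height (cm), weight (kg), BMI (kg/m^2), waist and hip
circumference (cm), GGT (U/L), waist-hip ratio (dimensionless), smoking
status (boolean) and weekly alcohol servings (count).
"""

from __future__ import annotations

import datetime as dt
import json
import re
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from .errors import ParseError, ValidationError

__all__ = [
    "Sex",
    "Parameter",
    "CodeSystem",
    "Patient",
    "MeasurementEvent",
    "DiagnosisEvent",
    "TextEvent",
    "EventStream",
    "read_events",
    "write_events",
    "validate_stream",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Parameter(str, Enum):
    FASTING_GLUCOSE = "fasting_glucose"
    HEIGHT = "height"
    WEIGHT = "weight"
    BMI = "bmi"
    WAIST_CIRCUMFERENCE = "waist_circumference"
    HIP_CIRCUMFERENCE = "hip_circumference"
    GGT = "ggt"
    WHR = "whr"
    SMOKING_STATUS = "smoking_status"
    ALCOHOL_SERVINGS_PER_WEEK = "alcohol_servings_per_week"


#: Parameters whose value is a boolean rather than a number.
BOOLEAN_PARAMETERS = frozenset({Parameter.SMOKING_STATUS})

#: Waist-hip ratio plausibility window (dimensionless).
WHR_RANGE = (0.3, 2.0)


class CodeSystem(str, Enum):
    ICD10 = "ICD-10"
    ICPC2 = "ICPC-2"


# Dotted ICD-10 ("F10.1", "K70", "C22.0") and plain ICPC-2 ("P15") syntax.
_ICD10_RE = re.compile(r"^[A-TV-Z]\d{2}(?:\.\d{1,2})?$")
_ICPC2_RE = re.compile(r"^[A-Z]\d{2}$")


def code_is_valid(system: CodeSystem, code: str) -> bool:
    pattern = _ICD10_RE if system is CodeSystem.ICD10 else _ICPC2_RE
    return bool(pattern.match(code))


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: Sex
    birth_date: dt.date


@dataclass(frozen=True)
class MeasurementEvent:
    date: dt.date
    parameter: Parameter
    value: float | bool
    #: Provenance of the record: "structured" for ordinary measurements,
    #: "simulated" for scenario-injected values.
    source: str = "structured"


@dataclass(frozen=True)
class DiagnosisEvent:
    date: dt.date
    system: CodeSystem
    code: str


@dataclass(frozen=True)
class TextEvent:
    date: dt.date
    text: str


Event = MeasurementEvent | DiagnosisEvent | TextEvent


@dataclass(frozen=True)
class EventStream:
    """One patient's demographics plus their date-ordered event history."""

    patient: Patient
    events: tuple[Event, ...] = ()

    def __post_init__(self):
        # Stable sort keeps same-date file order, which downstream tie-breaks
        # rely on (last record on a date wins).
        object.__setattr__(self, "events", tuple(sorted(self.events, key=lambda e: e.date)))

    def measurements(self, parameter: Parameter | None = None) -> list[MeasurementEvent]:
        out = [e for e in self.events if isinstance(e, MeasurementEvent)]
        if parameter is not None:
            out = [e for e in out if e.parameter is parameter]
        return out

    def diagnoses(self) -> list[DiagnosisEvent]:
        return [e for e in self.events if isinstance(e, DiagnosisEvent)]

    def texts(self) -> list[TextEvent]:
        return [e for e in self.events if isinstance(e, TextEvent)]

    def with_events(self, extra: Iterable[Event]) -> "EventStream":
        return replace(self, events=self.events + tuple(extra))


# ---------------------------------------------------------------------------
# Validation

def _violations_for_event(event: Event, patient: Patient, index: int) -> list[str]:
    where = f"event {index} ({event.date.isoformat()})"
    out: list[str] = []
    if event.date <= patient.birth_date:
        out.append(f"{where}: event date not after birth_date {patient.birth_date.isoformat()}")
    if isinstance(event, MeasurementEvent):
        if event.parameter in BOOLEAN_PARAMETERS:
            if not isinstance(event.value, bool):
                out.append(f"{where}: {event.parameter.value} requires a boolean value")
        else:
            if isinstance(event.value, bool) or not isinstance(event.value, (int, float)):
                out.append(f"{where}: {event.parameter.value} requires a numeric value")
            elif event.value < 0:
                out.append(f"{where}: {event.parameter.value} must be non-negative, got {event.value}")
            elif event.parameter is Parameter.WHR and not (WHR_RANGE[0] < event.value < WHR_RANGE[1]):
                out.append(
                    f"{where}: whr must lie in ({WHR_RANGE[0]}, {WHR_RANGE[1]}), got {event.value}"
                )
    elif isinstance(event, DiagnosisEvent):
        if not code_is_valid(event.system, event.code):
            out.append(f"{where}: code {event.code!r} does not match {event.system.value} syntax")
    elif isinstance(event, TextEvent):
        if not event.text.strip():
            out.append(f"{where}: text event is empty")
    return out


def validate_stream(stream: EventStream) -> list[str]:
    """Return human-readable invariant violations; empty list means valid.

    Never raises and never mutates its input.
    """
    out: list[str] = []
    if not stream.patient.patient_id:
        out.append("patient_id is empty")
    for i, event in enumerate(stream.events):
        out.extend(_violations_for_event(event, stream.patient, i))
    for a, b in zip(stream.events, stream.events[1:]):
        if a.date > b.date:  # defensive: construction sorts
            out.append("events are not sorted by date")
            break
    return out


# ---------------------------------------------------------------------------
# Line-delimited I/O

def _date(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def _event_to_obj(patient_id: str, event: Event) -> dict:
    if isinstance(event, MeasurementEvent):
        obj = {
            "type": "measurement",
            "patient_id": patient_id,
            "date": event.date.isoformat(),
            "parameter": event.parameter.value,
            "value": event.value,
        }
        if event.source != "structured":
            obj["source"] = event.source
        return obj
    if isinstance(event, DiagnosisEvent):
        return {
            "type": "diagnosis",
            "patient_id": patient_id,
            "date": event.date.isoformat(),
            "system": event.system.value,
            "code": event.code,
        }
    return {
        "type": "text",
        "patient_id": patient_id,
        "date": event.date.isoformat(),
        "text": event.text,
    }


def _obj_to_event(obj: dict, line_number: int) -> Event:
    kind = obj.get("type")
    try:
        date = _date(obj["date"])
        if kind == "measurement":
            try:
                parameter = Parameter(obj["parameter"])
            except ValueError:
                raise ValidationError(
                    f"line {line_number}: unknown parameter {obj['parameter']!r}"
                ) from None
            value = obj["value"]
            if parameter not in BOOLEAN_PARAMETERS:
                value = float(value)
            return MeasurementEvent(date, parameter, value, obj.get("source", "structured"))
        if kind == "diagnosis":
            return DiagnosisEvent(date, CodeSystem(obj["system"]), obj["code"])
        if kind == "text":
            return TextEvent(date, obj["text"])
    except KeyError as exc:
        raise ParseError(f"missing field {exc}", line_number) from None
    raise ParseError(f"unknown record type {kind!r}", line_number)


def read_events(path: str | Path) -> list[EventStream]:
    """Read a JSON-Lines cohort file into one :class:`EventStream` per patient.

    Raises
    ------
    ParseError
        for malformed lines (names the line number).
    ValidationError
        for unknown parameters, duplicate/missing patient records, or any
        stream-level invariant violation (e.g. an event predating birth).
    """
    patients: dict[str, Patient] = {}
    events: dict[str, list[Event]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON ({exc.msg})", lineno) from None
            if not isinstance(obj, dict):
                raise ParseError("record is not a JSON object", lineno)
            pid = obj.get("patient_id")
            if not pid:
                raise ParseError("record lacks patient_id", lineno)
            if obj.get("type") == "patient":
                if pid in patients:
                    raise ValidationError(f"line {lineno}: duplicate patient record for {pid!r}")
                try:
                    patients[pid] = Patient(pid, Sex(obj["sex"]), _date(obj["birth_date"]))
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"bad patient record ({exc})", lineno) from None
            else:
                events.setdefault(pid, []).append(_obj_to_event(obj, lineno))

    missing = set(events) - set(patients)
    if missing:
        raise ValidationError(f"events for unknown patient(s): {sorted(missing)}")

    streams = [EventStream(patients[pid], tuple(events.get(pid, []))) for pid in patients]
    for stream in streams:
        problems = validate_stream(stream)
        if problems:
            raise ValidationError(
                f"patient {stream.patient.patient_id!r}: " + "; ".join(problems)
            )
    return streams


def write_events(streams: Sequence[EventStream], path: str | Path) -> None:
    """Write streams in canonical order: by patient_id, then event date.

    Output is byte-deterministic and round-trips through :func:`read_events`.
    """
    seen: set[str] = set()
    for stream in streams:
        pid = stream.patient.patient_id
        if pid in seen:
            raise ValidationError(f"duplicate patient_id {pid!r} in cohort")
        seen.add(pid)
        problems = validate_stream(stream)
        if problems:
            raise ValidationError(f"patient {pid!r}: " + "; ".join(problems))

    with open(path, "w", encoding="utf-8") as fh:
        for stream in sorted(streams, key=lambda s: s.patient.patient_id):
            p = stream.patient
            fh.write(
                json.dumps(
                    {
                        "type": "patient",
                        "patient_id": p.patient_id,
                        "sex": p.sex.value,
                        "birth_date": p.birth_date.isoformat(),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
            for event in stream.events:  # already date-sorted
                fh.write(json.dumps(_event_to_obj(p.patient_id, event), ensure_ascii=False) + "\n")
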