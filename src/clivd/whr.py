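"""Waist-hip-ratio availability scenarios and categorical WHR binning.

WHR is the risk model's key adiposity input but is absent from structured
national-repository data, so its effect is studied by simulation: WHR
values are drawn from sex-specific normal distributions (mean 0.96 for
men, 0.84 for women, variance 0.07) and injected into patient timelines
under three modes — *document coverage* (each document date independently
carries a WHR with a given probability, e.g. 0.5% or 10%), and two
*self-report* modes (one value per patient, exact or categorical).

The stated variance is taken literally by default (SD ~= 0.265, which is
physiologically wide); set ``variance_is_sd=True`` to read it as a
standard deviation instead.  Draws are truncated to the plausibility
window (0.3, 2.0) unless ``truncate=False``.

Categorical schemes replace an exact WHR by its bin's (min, max) bounds,
with the outer bins clamped to the substitution defaults (0.7, 1.3) —
mirroring a questionnaire where a person picks the body-shape image
closest to their own instead of measuring.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DomainError
from .records import EventStream, MeasurementEvent, Parameter, Sex, WHR_RANGE
from .timeline import age_at

__all__ = [
    "WhrScenario",
    "WhrBinScheme",
    "BIN_SCHEMES",
    "draw_whr",
    "apply_scenario",
    "bin_whr",
]

#: Substitution defaults; outer bins clamp to these.
WHR_DEFAULT_BOUNDS = (0.7, 1.3)


@dataclass(frozen=True)
class WhrScenario:
    mode: str = "document_coverage"  # or self_report_exact / self_report_categorical
    coverage_fraction: float = 0.005
    category_scheme: str = "exact"  # exact / three_bin / five_bin
    male_mean: float = 0.96
    female_mean: float = 0.84
    variance: float = 0.07
    variance_is_sd: bool = False
    truncate: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("document_coverage", "self_report_exact", "self_report_categorical"):
            raise ConfigError(f"unknown scenario mode {self.mode!r}")
        if not 0.0 <= self.coverage_fraction <= 1.0:
            raise ConfigError("coverage_fraction must lie in [0, 1]")
        if self.category_scheme not in ("exact", "three_bin", "five_bin"):
            raise ConfigError(f"unknown category scheme {self.category_scheme!r}")
        for name, mean in (("male_mean", self.male_mean), ("female_mean", self.female_mean)):
            if not 0.5 < mean < 1.5:
                raise ConfigError(f"{name} must lie in (0.5, 1.5)")
        if self.variance <= 0:
            raise ConfigError("variance must be positive")

    @property
    def sd(self) -> float:
        return self.variance if self.variance_is_sd else float(np.sqrt(self.variance))

    def mean_for(self, sex: Sex) -> float:
        return self.male_mean if sex is Sex.MALE else self.female_mean


def draw_whr(
    sex: Sex,
    scenario: WhrScenario,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw WHR value(s) from the scenario's sex-specific distribution.

    Truncation (when enabled) resamples outside (0.3, 2.0); reproducible
    given the generator state.
    """
    n = 1 if size is None else int(size)
    out = rng.normal(scenario.mean_for(sex), scenario.sd, size=n)
    if scenario.truncate:
        lo, hi = WHR_RANGE
        bad = (out <= lo) | (out >= hi)
        while bad.any():
            out[bad] = rng.normal(scenario.mean_for(sex), scenario.sd, size=int(bad.sum()))
            bad = (out <= lo) | (out >= hi)
    return float(out[0]) if size is None else out


def apply_scenario(
    cohort: list[EventStream],
    scenario: WhrScenario,
    rng: np.random.Generator | None = None,
    min_age: int = 40,
) -> list[EventStream]:
    """Populate timelines with simulated WHR measurements.

    ``document_coverage``: each distinct event date independently carries a
    WHR with probability ``coverage_fraction``.  Self-report modes: one WHR
    event per patient at their first eligible date (first event date at or
    after the ``min_age`` birthday).  Added events carry
    ``source="simulated"``; original events and streams are untouched.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    out: list[EventStream] = []
    for stream in cohort:
        sex = stream.patient.sex
        extra: list[MeasurementEvent] = []
        if scenario.mode == "document_coverage":
            dates = sorted({e.date for e in stream.events})
            if dates:
                hits = rng.random(len(dates)) < scenario.coverage_fraction
                for date, hit in zip(dates, hits):
                    if hit:
                        extra.append(
                            MeasurementEvent(
                                date, Parameter.WHR, draw_whr(sex, scenario, rng), "simulated"
                            )
                        )
        else:
            eligible = [
                e.date
                for e in stream.events
                if age_at(stream.patient.birth_date, e.date) >= min_age
            ]
            if eligible:
                extra.append(
                    MeasurementEvent(
                        min(eligible), Parameter.WHR, draw_whr(sex, scenario, rng), "simulated"
                    )
                )
        out.append(stream.with_events(extra) if extra else stream)
    return out


@dataclass(frozen=True)
class WhrBinScheme:
    """Ordered inner edges partitioning the WHR plausibility window.

    A value's substitution bounds are its enclosing bin's edges, with the
    outermost edges clamped to the (0.7, 1.3) defaults; a value falling
    outside the clamp extends its own bin just enough to enclose it.
    ``edges=()`` is the exact scheme: bounds (value, value).
    """

    edges: tuple[float, ...] = ()
    clamp: tuple[float, float] = WHR_DEFAULT_BOUNDS

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ConfigError("bin edges must be strictly increasing")


#: Default schemes; edges are nested so finer schemes refine coarser ones.
BIN_SCHEMES: dict[str, WhrBinScheme] = {
    "exact": WhrBinScheme(()),
    "three_bin": WhrBinScheme((0.85, 1.00)),
    "five_bin": WhrBinScheme((0.80, 0.85, 1.00, 1.10)),
}


def bin_whr(value: float, scheme: WhrBinScheme) -> tuple[float, float]:
    """Substitution bounds for a WHR value under a categorical scheme."""
    lo, hi = WHR_RANGE
    if not lo < value < hi:
        raise DomainError(f"WHR {value} outside plausible range ({lo}, {hi})")
    if not scheme.edges:
        return (value, value)
    bin_lo, bin_hi = scheme.clamp
    for edge in scheme.edges:
        if value < edge:
            bin_hi = edge
            break
        bin_lo = edge
    else:
        bin_hi = scheme.clamp[1]
    return (min(bin_lo, value), max(bin_hi, value))
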