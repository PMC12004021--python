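"""Risk function, exclusion screening, default substitution, categorization."""

import datetime as dt
import math

import numpy as np
import pytest
import yaml
from dataclasses import replace
from importlib import resources

from clivd.errors import ConfigError, ConsistencyError, DomainError
from clivd.records import CodeSystem, DiagnosisEvent, MeasurementEvent, Parameter, Sex
from clivd.risk import (
    DEFAULTS,
    ExclusionReason,
    InputInterval,
    InputVector,
    RiskCategory,
    RiskCoefficients,
    RiskInterval,
    Variant,
    categorize,
    clivd_score,
    derive_diabetes,
    load_model_config,
    resolve_inputs,
    risk_interval,
    screen_exclusions,
)
from clivd.timeline import POLICY_PRESETS, state_at

from conftest import make_stream

INFINITE = POLICY_PRESETS["infinite"]


def state_for(events=(), birth=dt.date(1965, 6, 15), sex=Sex.MALE, date=dt.date(2020, 12, 31)):
    return state_at(make_stream(sex=sex, birth=birth, events=events), date, INFINITE)


# ---------------------------------------------------------------------------
# Independent oracle: a from-scratch transcription of the scoring formula
# reading the same coefficient file, sharing no code with the package path.


def oracle_score(vec: InputVector) -> float:
    raw = yaml.safe_load(
        resources.files("clivd.data")
        .joinpath("clivd_coefficients_synthetic.yaml")
        .read_text(encoding="utf-8")
    )
    block = raw["models"][vec.variant.value]
    c, z = block["coefficients"], block.get("centering", {})
    lp = 0.0
    lp += c["male"] if vec.sex is Sex.MALE else 0.0
    lp += c["age_per_year"] * (vec.age - z.get("age_years", 0.0))
    lp += c["smoker"] if vec.smoker else 0.0
    lp += c["alcohol_per_weekly_serving"] * vec.alcohol_servings_per_week
    lp += c["whr_per_unit"] * (vec.whr - z.get("whr", 0.0))
    lp += c["diabetes"] if vec.diabetes else 0.0
    if vec.variant is Variant.LAB:
        lp += c["log_ggt"] * (math.log(vec.ggt) - z.get("log_ggt", 0.0))
    return 1.0 - block["baseline_survival_10y"] ** math.exp(lp)


def random_vector(rng) -> InputVector:
    variant = Variant.LAB if rng.random() < 0.5 else Variant.NONLAB
    return InputVector(
        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        age=int(rng.integers(40, 71)),
        smoker=bool(rng.random() < 0.5),
        alcohol_servings_per_week=float(rng.uniform(0, 49)),
        diabetes=bool(rng.random() < 0.5),
        whr=float(rng.uniform(0.7, 1.3)),
        ggt=float(rng.uniform(10, 300)) if variant is Variant.LAB else None,
        variant=variant,
    )


def test_score_matches_independent_transcription(model):
    """Implementation vs from-scratch formula transcription on 25 vectors."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        vec = random_vector(rng)
        got = clivd_score(vec, model.models[vec.variant])
        assert got == pytest.approx(oracle_score(vec), abs=1e-6)


def test_score_is_deterministic_and_bounded(model):
    vec = random_vector(np.random.default_rng(7))
    coeffs = model.models[vec.variant]
    assert clivd_score(vec, coeffs) == clivd_score(vec, coeffs)
    assert 0.0 <= clivd_score(vec, coeffs) <= 1.0


def test_zeroed_coefficients_reduce_to_baseline():
    coeffs = RiskCoefficients(
        variant=Variant.NONLAB,
        baseline_survival_10y=0.98,
        coefficients={k: 0.0 for k in
                      ("male", "age_per_year", "smoker", "alcohol_per_weekly_serving",
                       "whr_per_unit", "diabetes")},
        centering={},
    )
    vec = InputVector(Sex.MALE, 60, True, 30.0, True, 1.2)
    assert clivd_score(vec, coeffs) == pytest.approx(1.0 - 0.98)


def test_score_monotone_in_each_risk_factor(model):
    """Published effect directions: every risk factor increases risk."""
    coeffs = model.models[Variant.NONLAB]
    base = InputVector(Sex.FEMALE, 55, False, 5.0, False, 0.9)
    r0 = clivd_score(base, coeffs)
    for bumped in (
        replace(base, sex=Sex.MALE),
        replace(base, age=65),
        replace(base, smoker=True),
        replace(base, alcohol_servings_per_week=25.0),
        replace(base, diabetes=True),
        replace(base, whr=1.1),
    ):
        assert clivd_score(bumped, coeffs) > r0
    lab = model.models[Variant.LAB]
    lab_lo = replace(base, variant=Variant.LAB, ggt=20.0)
    lab_hi = replace(base, variant=Variant.LAB, ggt=200.0)
    assert clivd_score(lab_hi, lab) > clivd_score(lab_lo, lab)


def test_lab_variant_requires_ggt(model):
    vec = InputVector(Sex.MALE, 55, False, 0.0, False, 0.9, ggt=None, variant=Variant.LAB)
    with pytest.raises(DomainError):
        clivd_score(vec, model.models[Variant.LAB])


# ---------------------------------------------------------------------------
# Exclusion screening


class TestExclusions:
    def test_age_below_window(self, model):
        state = state_for(birth=dt.date(1986, 1, 1))  # 34 years old in 2020
        result = screen_exclusions(state, model)
        assert result.excluded and result.reasons == {ExclusionReason.AGE_OUT_OF_RANGE}

    def test_age_above_window(self, model):
        state = state_for(birth=dt.date(1948, 1, 1))  # 72
        assert ExclusionReason.AGE_OUT_OF_RANGE in screen_exclusions(state, model).reasons

    def test_window_edges_inclusive(self, model):
        for birth in (dt.date(1980, 1, 1), dt.date(1950, 12, 31)):  # ages 40 and 70
            assert not screen_exclusions(state_for(birth=birth), model).excluded

    @pytest.mark.parametrize(
        "code, reason",
        [
            ("K70.3", ExclusionReason.LIVER_DISEASE_DX),
            ("K77", ExclusionReason.LIVER_DISEASE_DX),
            ("C22.0", ExclusionReason.LIVER_DISEASE_DX),
            ("B18.2", ExclusionReason.VIRAL_HEPATITIS_DX),
            ("B18", ExclusionReason.VIRAL_HEPATITIS_DX),
        ],
    )
    def test_diagnosis_exclusions(self, model, code, reason):
        state = state_for(events=[DiagnosisEvent(dt.date(2015, 1, 1), CodeSystem.ICD10, code)])
        result = screen_exclusions(state, model)
        assert result.excluded and result.reasons == {reason}

    def test_nearby_codes_do_not_exclude(self, model):
        state = state_for(
            events=[
                DiagnosisEvent(dt.date(2015, 1, 1), CodeSystem.ICD10, "K69.9"),
                DiagnosisEvent(dt.date(2015, 1, 1), CodeSystem.ICD10, "C22.1"),
                DiagnosisEvent(dt.date(2015, 1, 1), CodeSystem.ICD10, "B17.9"),
            ]
        )
        assert not screen_exclusions(state, model).excluded

    def test_abstainer_needs_text_confirmation_by_default(self, model):
        state = state_for(events=[DiagnosisEvent(dt.date(2015, 1, 1), CodeSystem.ICD10, "F10.20")])
        assert not screen_exclusions(state, model).excluded
        confirmed = screen_exclusions(state, model, abstinence_evidence=True)
        assert ExclusionReason.ALCOHOL_ABSTAINER_PRIOR_USE in confirmed.reasons

    def test_abstainer_code_only_mode(self, model):
        strict = replace(model, abstainer_mode="code_only")
        state = state_for(events=[DiagnosisEvent(dt.date(2015, 1, 1), CodeSystem.ICD10, "F10.25")])
        assert ExclusionReason.ALCOHOL_ABSTAINER_PRIOR_USE in screen_exclusions(state, strict).reasons


# ---------------------------------------------------------------------------
# Diabetes derivation


class TestDeriveDiabetes:
    def glucose_state(self, value):
        return state_for(
            events=[MeasurementEvent(dt.date(2020, 3, 1), Parameter.FASTING_GLUCOSE, value)]
        )

    def test_glucose_at_or_above_threshold(self, model):
        assert derive_diabetes(self.glucose_state(7.4), model) is True
        assert derive_diabetes(self.glucose_state(7.0), model) is True

    def test_glucose_below_threshold(self, model):
        assert derive_diabetes(self.glucose_state(5.1), model) is False

    def test_diagnosis_code_wins(self, model):
        state = state_for(events=[DiagnosisEvent(dt.date(2016, 1, 1), CodeSystem.ICD10, "E11.9")])
        assert derive_diabetes(state, model) is True

    def test_no_evidence_means_false_by_default(self, model):
        assert derive_diabetes(state_for(), model) is False

    def test_unknown_mode_returns_none(self, model):
        unknown = replace(model, missing_diabetes_unknown=True)
        assert derive_diabetes(state_for(), unknown) is None


# ---------------------------------------------------------------------------
# Default substitution


class TestResolveInputs:
    def test_all_missing_uses_extreme_defaults(self, model):
        # Table-style behaviour for diabetes: treat no-evidence as unknown.
        cfg = replace(model, missing_diabetes_unknown=True)
        state = state_for(birth=dt.date(1970, 6, 1))  # male, 50
        interval = resolve_inputs(state, cfg)
        lo, hi = interval.min_inputs, interval.max_inputs
        assert (lo.smoker, lo.alcohol_servings_per_week, lo.diabetes, lo.whr) == (
            False, 0.0, False, 0.7)
        assert (hi.smoker, hi.alcohol_servings_per_week, hi.diabetes, hi.whr) == (
            True, 49.0, True, 1.3)
        assert interval.substituted == {"smoker", "alcohol_servings_per_week", "diabetes", "whr"}
        assert lo.variant is Variant.NONLAB  # missing GGT switches variant

    def test_missing_diabetes_defaults_false_per_default_config(self, model):
        interval = resolve_inputs(state_for(), model)
        assert interval.min_inputs.diabetes is False
        assert interval.max_inputs.diabetes is False
        assert "diabetes" not in interval.substituted

    def test_observed_value_enters_both_ends(self, model):
        state = state_for(
            events=[
                MeasurementEvent(
                    dt.date(2020, 1, 1), Parameter.ALCOHOL_SERVINGS_PER_WEEK, 10.0
                )
            ]
        )
        interval = resolve_inputs(state, model)
        assert interval.min_inputs.alcohol_servings_per_week == 10.0
        assert interval.max_inputs.alcohol_servings_per_week == 10.0
        assert "alcohol_servings_per_week" not in interval.substituted

    def test_observed_ggt_selects_lab_variant(self, model):
        state = state_for(events=[MeasurementEvent(dt.date(2020, 1, 1), Parameter.GGT, 55.0)])
        interval = resolve_inputs(state, model)
        assert interval.min_inputs.variant is Variant.LAB
        assert interval.min_inputs.ggt == 55.0

    def test_age_outside_window_is_domain_error(self, model):
        with pytest.raises(DomainError):
            resolve_inputs(state_for(birth=dt.date(1990, 1, 1)), model)

    def test_min_cannot_exceed_max(self):
        lo = InputVector(Sex.MALE, 50, False, 20.0, False, 0.9)
        hi = InputVector(Sex.MALE, 50, False, 10.0, False, 0.9)
        with pytest.raises(ConsistencyError):
            InputInterval(lo, hi, frozenset({"alcohol_servings_per_week"}))


# ---------------------------------------------------------------------------
# Interval scoring and categorization


class TestRiskInterval:
    def test_fully_observed_gives_width_zero(self, model):
        vec = InputVector(Sex.MALE, 55, True, 20.0, True, 1.0)
        interval = risk_interval(InputInterval(vec, vec, frozenset()), model)
        assert interval.width == 0.0

    def test_partial_knowledge_narrows_the_interval(self, model):
        state_unknown = state_for(birth=dt.date(1970, 6, 1))
        state_alcohol = state_for(
            birth=dt.date(1970, 6, 1),
            events=[MeasurementEvent(dt.date(2020, 1, 1), Parameter.ALCOHOL_SERVINGS_PER_WEEK, 10.0)],
        )
        wide = risk_interval(resolve_inputs(state_unknown, model), model)
        narrow = risk_interval(resolve_inputs(state_alcohol, model), model)
        assert narrow.width < wide.width
        assert wide.risk_min <= narrow.risk_min <= narrow.risk_max <= wide.risk_max

    def test_invalid_interval_construction_rejected(self):
        with pytest.raises(ConsistencyError):
            RiskInterval(0.4, 0.2)
        with pytest.raises(ConsistencyError):
            RiskInterval(-0.1, 0.2)

    def test_substituting_inner_observation_contains_interval(self, model):
        """Replacing a default by any observed value inside the default
        bounds yields a risk interval nested in the original (monotone
        score), across a grid of cases."""
        rng = np.random.default_rng(3)
        for _ in range(40):
            state = state_for(birth=dt.date(1968, 6, 1),
                              sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE)
            wide = risk_interval(resolve_inputs(state, model), model)
            whr = float(rng.uniform(*DEFAULTS["whr"]))
            observed = state_for(
                birth=dt.date(1968, 6, 1), sex=state.sex,
                events=[MeasurementEvent(dt.date(2020, 1, 1), Parameter.WHR, whr)],
            )
            narrow = risk_interval(resolve_inputs(observed, model), model)
            assert wide.risk_min <= narrow.risk_min + 1e-12
            assert narrow.risk_max <= wide.risk_max + 1e-12


class TestCategorize:
    @pytest.mark.parametrize(
        "interval, expected",
        [
            ((0.03, 0.04), RiskCategory.LOW),
            ((0.12, 0.15), RiskCategory.HIGH),
            ((0.06, 0.08), RiskCategory.MODERATE),
            ((0.03, 0.20), RiskCategory.NOT_SPECIFIED),
            ((0.10, 0.10), RiskCategory.HIGH),       # min at the high cutoff
            ((0.04, 0.05), RiskCategory.NOT_SPECIFIED),  # max exactly at low cutoff
            ((0.06, 0.30), RiskCategory.MODERATE),   # min above low, below high
            ((0.05, 0.06), RiskCategory.NOT_SPECIFIED),  # min exactly at low cutoff
        ],
    )
    def test_worked_examples(self, interval, expected):
        assert categorize(RiskInterval(*interval)) is expected

    def test_total_and_single_valued_on_dense_grid(self):
        grid = np.linspace(0.0, 1.0, 101)
        for lo in grid:
            for hi in grid[grid >= lo]:
                category = categorize(RiskInterval(float(lo), float(hi)))
                assert isinstance(category, RiskCategory)

    def test_degenerate_cutoffs_collapse_not_specified_for_points(self):
        """With low_cut == high_cut every point interval gets a definite
        category: the not-specified band vanishes."""
        for r in np.linspace(0.0, 1.0, 51):
            category = categorize(RiskInterval(float(r), float(r)), cutoffs=(0.08, 0.08))
            assert category is not RiskCategory.NOT_SPECIFIED

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ConfigError):
            categorize(RiskInterval(0.01, 0.02), cutoffs=(0.2, 0.1))


def test_coefficient_loading_requires_all_names():
    with pytest.raises(ConfigError):
        RiskCoefficients(
            variant=Variant.NONLAB,
            baseline_survival_10y=0.99,
            coefficients={"male": 0.5},
            centering={},
        )
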