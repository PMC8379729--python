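"""Shared fixtures: a small synthetic population, a drawn sample, and a
record factory for classification unit tests."""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from fpequity.fp_status import attach_status
from fpequity.synthetic_data import DesignParams, PopulationSpec, draw_survey, generate_census


def small_population_spec() -> PopulationSpec:
    """A scaled-down population (a few thousand women) for fast tests."""
    return PopulationSpec(n_strata=4, psus_per_stratum=60, psu_household_range=(20, 40))


@pytest.fixture(scope="session")
def small_spec() -> PopulationSpec:
    return small_population_spec()


@pytest.fixture(scope="session")
def small_census(small_spec):
    """(census, truth, internal) for the small population, fixed seed."""
    return generate_census(small_spec, seed=123, return_internal=True)


@pytest.fixture(scope="session")
def sample_df(small_census):
    census, _truth, _internal = small_census
    return draw_survey(census, DesignParams(n_psus_per_stratum=12), seed=99)


@pytest.fixture(scope="session")
def classified(sample_df):
    return attach_status(sample_df)


_RECORD_DEFAULTS = dict(
    woman_id="W1",
    stratum_id="S01",
    psu_id="P1",
    household_id="H1",
    weight=1.0,
    age_years=30,
    in_union=True,
    education_level="primary",
    wealth_quintile="Q3",
    region_code="R01",
    currently_pregnant=False,
    pregnancy_wantedness="not_applicable",
    fertility_preference="wants_no_more",
    current_method="none",
    self_reported_infecund=False,
    menopause_hysterectomy_or_never_menstruated=False,
    months_since_last_period=3.0,
    postpartum_amenorrheic=False,
    years_in_union=3.0,
    used_contraception_past_5y=True,
    pregnant_in_past_5y=False,
)


def make_record(**overrides) -> SimpleNamespace:
    """A fully observed woman record (attribute access) with overrides."""
    d = dict(_RECORD_DEFAULTS)
    d.update(overrides)
    return SimpleNamespace(**d)


@pytest.fixture
def record_factory():
    return make_record
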