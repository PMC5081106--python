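import numpy as np
import pytest

from glucotrend.synthetic import WorldConfig, build_world, make_survey_plan, simulate_surveys


def flat_world_config(**overrides) -> WorldConfig:
    """A world whose true surface is exactly constant over countries and
    years: no trend, no hierarchical deviations, no smooth wiggle, no
    covariate effects, no age gradient."""
    base = dict(
        sexes=("female",),
        trend_per_decade=0.0, sex_level_offset=0.0, sex_trend_offset=0.0,
        sd_super_intercept=0.0, sd_region_intercept=0.0, sd_country_intercept=0.0,
        sd_super_slope=0.0, sd_region_slope=0.0, sd_country_slope=0.0,
        sd_nonlinear={"world": 0.0, "super_region": 0.0, "region": 0.0,
                      "country": 0.0},
        age_amplitude=0.0, age_steepness=0.0,
        beta_education=0.0, beta_urbanisation=0.0, beta_food=0.0, beta_bmi=0.0,
        rural_urban_gap=0.0,
    )
    base.update(overrides)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def small_world():
    """Default-condition world (12 countries, both defaults for biases)."""
    return build_world(WorldConfig(sexes=("female",)), seed=11)


@pytest.fixture(scope="session")
def small_world_datapoints(small_world):
    plan = make_survey_plan(
        small_world, studies_per_country=6, seed=12, sexes=("female",)
    )
    return simulate_surveys(small_world, plan, seed=13)
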