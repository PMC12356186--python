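from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snakeroad.encounters import SnakeEncounter, SurveyEffort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_encounter(**kwargs):
    base = dict(
        species="Crotalus atrox",
        encounter_date=date(2017, 8, 4),
        survey_type="standardized",
        status="AOR",
        demo_class="male",
    )
    base.update(kwargs)
    return SnakeEncounter(**base)


@pytest.fixture
def atrox_adult():
    return make_encounter(svl_cm=78.0, tail_cm=7.0, weight_g=390.0, route_km=12.4)


@pytest.fixture
def mixed_community():
    """A handful of records spanning species, statuses and missing fields."""
    return [
        make_encounter(svl_cm=78.0, tail_cm=7.0, weight_g=390.0, route_km=12.4),
        make_encounter(status="DOR", svl_cm=95.5, tail_cm=8.1, weight_g=610.0,
                       route_km=3.0, impact_point="midbody"),
        make_encounter(species="Arizona elegans", demo_class="female",
                       svl_cm=62.0, tail_cm=11.5, weight_g=110.0, route_km=30.9),
        make_encounter(species="Arizona elegans", demo_class="unknown", status="DOR"),
        make_encounter(demo_class="juvenile", svl_cm=33.0, tail_cm=2.9,
                       weight_g=20.0, route_km=36.5,
                       encounter_date=date(2017, 9, 2)),
    ]


@pytest.fixture
def efforts_aug_sep():
    return [
        SurveyEffort(date(2017, 8, 5), "standardized", 74.0),
        SurveyEffort(date(2017, 8, 15), "standardized", 74.0),
        SurveyEffort(date(2017, 9, 10), "standardized", 74.0),
    ]


@pytest.fixture(scope="session")
def adult_table():
    """Synthetic adult modeling table, generated once per test session."""
    from snakeroad.synth import generate_atrox_adults

    return generate_atrox_adults(400, seed=12345)
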