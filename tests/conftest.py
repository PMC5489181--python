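from datetime import date

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from camrecap.survey import Primary, SurveyDesign

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_design():
    """Three primaries with K=2, including a 2-year survey gap."""
    prim = tuple(
        Primary(y, date(y, 2, 1), date(y, 2, 15), 2, "film")
        for y in (2000, 2001, 2003)
    )
    return SurveyDesign(prim, n_stations=5)


@pytest.fixture
def single_primary_design():
    prim = (Primary(2005, date(2005, 2, 1), date(2005, 3, 1), 4, "film"),)
    return SurveyDesign(prim, n_stations=5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
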