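import numpy as np
import pytest

from eventfuse.hazards import HazardSpec, SeasonCalendar
from eventfuse.likelihood import SurveySchedule


@pytest.fixture
def rng():
    return np.random.default_rng(20150117)


@pytest.fixture
def constant_spec():
    """Constant hazard of 0.01 per day."""
    return HazardSpec(log_rates=np.log([0.01]))


@pytest.fixture
def seasonal_spec():
    """The annual-survival-0.25 two-season design (hunting days 274-365)."""
    return HazardSpec(
        log_rates=np.log([0.0030335, 0.0060669]),
        season=SeasonCalendar(274, 365),
    )


@pytest.fixture
def weekly_schedule():
    return SurveySchedule.weekly(477.0)


def random_piecewise_spec(rng, max_intervals=5, t_max=100.0):
    """Random piecewise-constant hazard on [0, t_max] for property tests."""
    k = int(rng.integers(1, max_intervals + 1))
    cps = np.sort(rng.uniform(1.0, t_max - 1.0, size=k - 1))
    cps = np.unique(cps)
    log_rates = rng.uniform(-6.0, -1.0, size=cps.size + 1)
    return HazardSpec(log_rates=log_rates, change_points=cps)
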