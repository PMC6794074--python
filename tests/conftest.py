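import numpy as np
import pandas as pd
import pytest

from circadam import FlySimParams, LightSchedule, simulate_population
from circadam.schedule import Phase


@pytest.fixture(scope="session")
def ld_dd_schedule():
    """Standard protocol: 5 days LD12:12 then 6 days DD, lights-on 08:00."""
    return LightSchedule.ld_dd(5, 6)


@pytest.fixture(scope="session")
def dd_only_schedule():
    return LightSchedule([Phase(0, "DD")], 6)


@pytest.fixture(scope="session")
def small_population(ld_dd_schedule):
    """Four rhythmic flies over the full 11-day protocol (seeded)."""
    return simulate_population(
        [FlySimParams()] * 4, ld_dd_schedule, 11, seed=42
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
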