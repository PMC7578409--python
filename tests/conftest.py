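import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fptargets import ATConfig, Trajectory, project
from fptargets.synthetic import STYLIZED_LATE_TRUTH

settings.register_profile(
    "package",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def config() -> ATConfig:
    return ATConfig()


@pytest.fixture(scope="session")
def stylized_trajectory() -> Trajectory:
    """BAU projection of the stylized late-transition country (DS75 in 2051)."""
    return project(STYLIZED_LATE_TRUTH, "Stylized", 2019, 2140)


def linear_ds_trajectory(
    country: str = "Linear",
    demand: float = 0.8,
    ds0: float = 0.60,
    slope: float = 0.01,
    y0: int = 2019,
    y1: int = 2100,
) -> Trajectory:
    """Hand-built trajectory with constant demand and linearly rising DS.

    DS at year t is ``ds0 + slope * (t - y0)`` (capped at 0.95); the
    demand remainder is split evenly between traditional use and unmet
    need.  Handy because t* and all targets are simple arithmetic.
    """
    years = np.arange(y0, y1 + 1)
    ds = np.minimum(ds0 + slope * (years - y0), 0.95)
    modern = ds * demand
    rest = demand - modern
    return Trajectory(country, years, modern, rest / 2, rest / 2)
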