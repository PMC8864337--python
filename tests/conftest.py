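import numpy as np
import pytest

from skewsphere import (
    RandomStream,
    ScenarioSpec,
    SFvMLParams,
    sample_sfvml,
    to_cartesian,
)

# the four circle scenario configurations of the synthetic study
SCENARIOS = {
    1: dict(mu0=[1.0], zeta=10.0, eta=0.5, xi=-4.0, sigma=1.0),
    2: dict(mu0=[1.0], zeta=10.0, eta=0.5, xi=0.5, sigma=0.5, lam=-1.0),
    3: dict(mu0=[1.0], tau0=9.0, alpha=0.5, beta=5.0, xi=-4.0, sigma=1.0),
    4: dict(mu0=[0.5], tau0=0.01, alpha=0.5, beta=9.0, xi=0.5, sigma=0.5, lam=-2.0),
}


def scenario_spec(s: int, p: int = 2, **over) -> ScenarioSpec:
    kw = dict(SCENARIOS.get(s, {}), **over)
    return ScenarioSpec.from_scenario(s, p=p, **kw)


@pytest.fixture(scope="session")
def stream():
    return RandomStream(20240)


@pytest.fixture(scope="session")
def truth_circle():
    """The (mu, tau, gamma) = (3, 0.6, 1) skew-von Mises truth."""
    return SFvMLParams(mu=to_cartesian([3.0]), tau=0.6, gamma=[1.0])


@pytest.fixture(scope="session")
def truth_sphere():
    return SFvMLParams(mu=to_cartesian([1.0, 2.0]), tau=2.0, gamma=[1.0, -1.0])


@pytest.fixture(scope="session")
def circle_data_500(stream, truth_circle):
    return sample_sfvml(500, truth_circle, stream.child("circle-500"))


@pytest.fixture(scope="session")
def circle_data_50(stream, truth_circle):
    return sample_sfvml(50, truth_circle, stream.child("circle-50"))
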