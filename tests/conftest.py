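import numpy as np
import pytest

from tumorgl import GompertzParams, ImmunotherapyProfile, RadiationSchedule


@pytest.fixture
def untreated_antibody():
    """Untreated-arm effective parameters of the autoantibody experiment."""
    return GompertzParams(a=0.049, k=0.011, N0=100.0)


@pytest.fixture
def untreated_fibrosarcoma():
    """Untreated-arm effective parameters of the fibrosarcoma RT experiment."""
    return GompertzParams(a=0.054, k=0.0164, N0=50.0)


@pytest.fixture
def eight_gy_course():
    """Three fractions of 8 Gy on days 9, 10, 11; alpha=0.3, beta=alpha/10."""
    return RadiationSchedule((9.0, 10.0, 11.0), (8.0, 8.0, 8.0), alpha=0.3, beta=0.03)


@pytest.fixture
def constant_it():
    return ImmunotherapyProfile(gamma=0.02, I0=1.0, rho=0.0)


def random_gompertz(rng: np.random.Generator) -> GompertzParams:
    """Parameter draw covering the tested (a, k, N0) ranges."""
    return GompertzParams(
        a=rng.uniform(0.01, 0.2),
        k=rng.uniform(0.001, 0.2),
        N0=rng.uniform(1.0, 100.0),
    )
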