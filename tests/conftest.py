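import numpy as np
import pytest

from maglpet import FrameSchedule, InputFunction, RateConstants


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def default_input() -> InputFunction:
    return InputFunction(12.0, -12.0, 0.4, 4.0)


@pytest.fixture(scope="session")
def healthy_rates() -> RateConstants:
    # cerebral-cortex-like kinetics in the fast-CO2-efflux regime
    return RateConstants(K1=0.1075, k2=0.3, k3=0.6, kh=0.66)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
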