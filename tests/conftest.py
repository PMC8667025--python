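import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from presynmc import (Environment, KineticScheme, KineticState, RateKind, RateLaw,
                      Transition, build_calbindin_scheme, build_vdcc_scheme)


@pytest.fixture(scope="session")
def vdcc():
    return build_vdcc_scheme()


@pytest.fixture(scope="session")
def calbindin():
    return build_calbindin_scheme()


@pytest.fixture(scope="session")
def two_state():
    """Constant-rate two-state chain A <-> B, k01=1000/s, k10=500/s."""
    return KineticScheme(
        [KineticState("A", 0), KineticState("B", 1)],
        [Transition(0, 1, RateLaw(RateKind.CONSTANT, 1000.0)),
         Transition(1, 0, RateLaw(RateKind.CONSTANT, 500.0))],
        name="two_state")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
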