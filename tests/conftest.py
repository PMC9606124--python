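import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ligaseflux.synth import simulate_phase_schedule
from ligaseflux.types import KineticParams

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def quiescent_schedule():
    """Factory: single-cell G0 schedule over a given duration."""

    def make(duration=20.0):
        return simulate_phase_schedule(1, {"G0": 1.0}, duration=duration, seed=0)[0]

    return make


@pytest.fixture
def cycling_schedule():
    """Deterministic G1/S/G2/M schedule (19.6 h cycle)."""

    def make(duration=40.0, seed=0, cv=0.0):
        return simulate_phase_schedule(
            1, {"G1": 8.0, "S": 6.0, "G2": 5.0, "M": 0.6}, duration=duration,
            seed=seed, duration_cv=cv,
        )[0]

    return make


@pytest.fixture
def noiseless_params():
    def make(s=10.0, k=0.25, r0=None):
        return KineticParams(s=s, k_by_phase={p: k for p in ("G0", "G1", "S", "G2", "M")},
                             noise_cv=0.0, R0=r0)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
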