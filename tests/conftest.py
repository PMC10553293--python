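import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diffenc as de

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def mono800():
    return de.build_monopolar(target_b=800.0)


@pytest.fixture(scope="session")
def mono50():
    return de.build_monopolar(target_b=50.0)


@pytest.fixture(scope="session")
def vel800():
    return de.build_velocity_compensated(target_b=800.0)


@pytest.fixture(scope="session")
def accel_pair():
    return de.build_acceleration_compensated(target_b=800.0)


@pytest.fixture(scope="session")
def accel_rect_pair():
    """Acceleration-compensated build in the ideal rectangular limit."""
    return de.build_acceleration_compensated(ramp=0.0, target_b=800.0)


@pytest.fixture(scope="session")
def five_schemes():
    return de.build_all(target_b=800.0)


def random_spinecho_scheme(rng: np.random.Generator) -> de.EncodingScheme:
    """A random valid spin-echo scheme: trapezoid lobes on both sides."""
    ramp = rng.uniform(0.0, 2.0) * 1e-3
    refocus = 28e-3
    pulses = []
    t = 0.0
    for _ in range(rng.integers(1, 3)):
        dur = rng.uniform(2 * ramp + 1e-3, 8e-3)
        if t + dur > 23e-3:
            break
        amp = rng.uniform(5, 60) * np.sign(rng.uniform(-1, 1)) * 1e-6
        pulses.append(de.TrapezoidPulse(t, dur, ramp, amp))
        t += dur + rng.uniform(0, 2e-3)
    t = 33e-3
    for _ in range(rng.integers(1, 3)):
        dur = rng.uniform(2 * ramp + 1e-3, 8e-3)
        if t + dur > 56e-3:
            break
        amp = rng.uniform(5, 60) * np.sign(rng.uniform(-1, 1)) * 1e-6
        pulses.append(de.TrapezoidPulse(t, dur, ramp, amp))
        t += dur + rng.uniform(0, 2e-3)
    return de.EncodingScheme(tuple(pulses), refocus, 56e-3, label="random")
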