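import numpy as np
import pytest
from hypothesis import settings

from armkin import SynthSpec, generate_reach

settings.register_profile("armkin", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("armkin")

#: Canonical study conditions: a 300 mm, 1 s minimum-jerk reach at 200 Hz.
REACH_SPEC = SynthSpec(amplitude=300.0, duration=1.0, rate=200.0)


@pytest.fixture(scope="session")
def single_reach():
    """Noise-free single right-arm reach with targets and ground truth."""
    return generate_reach(REACH_SPEC)


@pytest.fixture(scope="session")
def both_sides_reach():
    """Noise-free two-sided, three-iteration reach fixture."""
    spec = SynthSpec(amplitude=300.0, duration=1.0, rate=200.0, n_iterations=3, arm_side="both")
    return generate_reach(spec)


@pytest.fixture()
def min_jerk_speed():
    """Analytic (not differentiated) minimum-jerk speed profile at 200 Hz."""
    from armkin import ScalarProfile

    D, T, fs = 300.0, 1.0, 200.0
    t = np.arange(round(T * fs)) / fs
    tau = t / T
    v = D / T * 30 * tau**2 * (1 - tau) ** 2
    return ScalarProfile(times=t, values=v, unit="mm/s", derivative_order=1)
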