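import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

FS = 1000.0


def tone(freq, fs=FS, duration=1.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def two_tone():
    """25 Hz + 150 Hz unit mixture with its components (fs=1000, 1 s)."""
    slow, fast = tone(25.0), tone(150.0)
    return slow + fast, slow, fast


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 subjects x 3 conditions x 1 trial, six muscles, fixed seed."""
    from emghht.synthetic_data import default_design, generate_cohort

    return generate_cohort(default_design(n_subjects=2, n_trials_per_condition=1, seed=42))
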