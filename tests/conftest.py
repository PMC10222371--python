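import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import swaycom as sc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def subject() -> sc.SubjectDescriptor:
    return sc.SubjectDescriptor(mass=70.0, height=1.75)


@pytest.fixture(scope="session")
def params(subject):
    return sc.derive_segment_parameters(subject)


@pytest.fixture(scope="session")
def inertias(params):
    return sc.composite_inertias(params)


@pytest.fixture(scope="session")
def unit_subject() -> sc.SubjectDescriptor:
    """M = 1 kg, H = 1 m: parameters equal the regression coefficients."""
    return sc.SubjectDescriptor(mass=1.0, height=1.0)


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))
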