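from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=40,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def unit_square() -> np.ndarray:
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


@pytest.fixture
def specimen_frame(rng):
    """A small ready-made experiment-1 specimen table."""
    from isoniche import simulate

    spec = simulate.default_spec(1)
    specimens, mesocosms = simulate.generate_experiment(spec, rng)
    return specimens, mesocosms
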