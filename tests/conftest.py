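import numpy as np
import pytest
from hypothesis import settings

from erpagree.simulate import SimConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced-size study for fast end-to-end tests (512 Hz keeps the whole
    0.5-30 Hz analysis band while cutting the sample count 4x)."""
    return SimConfig(
        sampling_rate=512.0, n_subjects=3, n_trials_per_intensity=4, seed=11
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
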