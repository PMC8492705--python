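import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import eegpsi as e

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage92():
    return e.default_montage()


@pytest.fixture(scope="session")
def grouping92(montage92):
    return e.default_grouping(montage92)


@pytest.fixture(scope="session")
def grid92():
    return e.default_momentum_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording(montage92, grouping92):
    """A short localized synthetic recording shared by read-only tests."""
    spec = e.SynthSpec(duration=3.0, seed=7,
                       localization=("Anterior L", "Anterior R"),
                       localization_strength=0.6)
    return e.generate_recording(spec, montage92, grouping92)


def random_probability_field(rng, n_channels, n_samples, fs=250.0):
    """Random valid probability field (columns sum to 1)."""
    P = rng.random((n_channels, n_samples)) + 1e-3
    return e.ProbabilityField(P / P.sum(axis=0), fs)
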