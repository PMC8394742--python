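import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from occfall import GeneratorConfig, features_frame, generate_dataset, load_traces

settings.register_profile(
    "occfall",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("occfall")


@pytest.fixture(scope="session")
def small_config():
    """Compact study conditions for fast protocol-level tests."""
    return GeneratorConfig(n_basic=8, n_standard=8, n_sporting=8,
                           n_falls=12, duration=8.0, n_subjects=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_dataset")
    return generate_dataset(small_config, out)


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    return features_frame(load_traces(small_dataset), "ABCDEFGHIJKL")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
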