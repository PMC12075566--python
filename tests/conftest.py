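import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metscreen.features import load_rules
from metscreen.synth import PlantedSpec, gen_planted_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def planted():
    """One planted-pharmacophore data set under the default study conditions."""
    return gen_planted_set(PlantedSpec(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
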