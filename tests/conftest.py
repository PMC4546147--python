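import numpy as np
import pytest
from hypothesis import settings

from phagemod import GeneratorConfig, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """One reduced-scale cohort (2 genomes per subgroup) shared by tests."""
    return generate_cohort(2, GeneratorConfig(scale=0.25), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
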