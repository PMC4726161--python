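import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitescan as ms

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cfg() -> ms.PipelineConfig:
    return ms.PipelineConfig()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_planted():
    """A 60 kb genome with 3 planted families of 4 copies each."""
    return ms.generate_planted_genome(
        seed=7, n_families=3, copies_per_family=4, genome_len=60_000
    )


@pytest.fixture(scope="session")
def small_summary(small_planted, cfg):
    genomes, _ = small_planted
    return ms.detect(genomes, cfg)
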