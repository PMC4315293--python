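import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cnvhotspots as ch

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset() -> ch.SyntheticDataset:
    """The default synthetic study conditions, one fixed seed."""
    return ch.generate(ch.SyntheticModel(seed=1))


@pytest.fixture(scope="session")
def toy_genome() -> ch.MappableGenome:
    """Single 1-Mb chromosome with two exclusion gaps (bitmap-oracle scale)."""
    return ch.MappableGenome(
        {"chrT": 1_000_000},
        [ch.GenomicInterval("chrT", 200_000, 230_000),
         ch.GenomicInterval("chrT", 700_000, 720_000)],
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
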