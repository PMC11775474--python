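from pathlib import Path

import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from faerspv.synthetic_faers import SimConfig, generate, write_quarter


@pytest.fixture(scope="session")
def small_quarter(tmp_path_factory) -> tuple[Path, object]:
    """A 3,000-case synthetic quarter on disk, with its ground truth."""
    d = tmp_path_factory.mktemp("quarter")
    truth = write_quarter(SimConfig(n_cases=3000, seed=11), d)
    return d, truth


@pytest.fixture(scope="session")
def small_tables():
    """In-memory tables of a 2,000-case synthetic quarter."""
    return generate(SimConfig(n_cases=2000, seed=7))
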