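from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def score_fixture_path() -> Path:
    return DATA_DIR / "mas_score_fixture.csv"


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort shared across tests (seed fixed)."""
    from asthmapred import GeneratorParams, generate_cohort

    records, sidecar = generate_cohort(GeneratorParams(seed=42))
    return records, sidecar
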