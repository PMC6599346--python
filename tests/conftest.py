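import pytest
from hypothesis import HealthCheck, settings

import fixensemble as fx

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_records():
    """One study-mimic synthetic table (215 variants, fixed seed)."""
    return fx.generate_variant_table(fx.study_mimic_config(seed=11))


@pytest.fixture(scope="session")
def study_frame(study_records):
    return fx.records_to_frame(study_records)


@pytest.fixture(scope="session")
def scored_frame(study_frame):
    """Study-mimic table with calls, scaled scores and combined functions."""
    return fx.score_table(study_frame)
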