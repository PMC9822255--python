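import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def records():
    from petmig import load_oligomers

    return load_oligomers()


@pytest.fixture(scope="session")
def records_by_name(records):
    return {r.acronym: r for r in records}
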