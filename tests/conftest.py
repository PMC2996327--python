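import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table2_profiles():
    """Packaged transcription of the checkpoint-mutant loss-rate table, keyed by strain."""
    from ofmkit.io import load_rates, packaged_table2_path

    return {p.strain: p for p in load_rates(packaged_table2_path())}
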