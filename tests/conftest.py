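import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def campaign():
    """One small synthetic campaign shared across tests (11 sites, 150 days)."""
    from dustrisk import default_config, generate_campaign

    return generate_campaign(default_config(seed=42))


@pytest.fixture(scope="session")
def composition(campaign):
    return campaign[0]


@pytest.fixture(scope="session")
def pm_series(campaign):
    return campaign[1]
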