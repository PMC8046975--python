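import pytest
from hypothesis import HealthCheck, settings

from microbuffer.pipeline import RunConfig, clean_all, run_pipeline
from microbuffer.synth import generate_campaign, paired_treeline_config

settings.register_profile(
    "default",
    settings(max_examples=25, deadline=None, derandomize=True,
             suppress_health_check=[HealthCheck.too_slow]))
settings.load_profile("default")

CAMPAIGN_SEED = 7


@pytest.fixture(scope="session")
def default_campaign():
    """One calibrated two-site year (records + ground truth)."""
    cfg = paired_treeline_config(seed=CAMPAIGN_SEED)
    records, truth = generate_campaign(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def clean_series(default_campaign):
    """Screened CleanSeries for every (site, position, variable)."""
    _, records, _ = default_campaign
    return clean_all(records)


@pytest.fixture(scope="session")
def air_series(clean_series):
    return {k: v for k, v in clean_series.items() if k[2] == "air_T"}


@pytest.fixture(scope="session")
def default_report(default_campaign):
    """Full pipeline report on the default campaign."""
    return run_pipeline(RunConfig(seed=CAMPAIGN_SEED))
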