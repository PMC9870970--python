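import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from crustpam.processing import process_records
from crustpam.simulate import SimConfig, simulate_campaign
from crustpam.summaries import summarize_campaign

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Reduced campaign: one sensor per treatment, 20 days."""
    return SimConfig(
        n_control=1, n_warming=1, end_date=dt.date(2016, 10, 10), seed=11
    )


@pytest.fixture(scope="session")
def small_campaign(small_config):
    return simulate_campaign(small_config)


@pytest.fixture(scope="session")
def small_processed(small_campaign):
    return process_records(small_campaign)


@pytest.fixture(scope="session")
def small_summaries(small_processed):
    return summarize_campaign(small_processed)


@pytest.fixture(scope="session")
def full_campaign():
    """Default 247-day, 6-sensor campaign at its reference settings."""
    return simulate_campaign(SimConfig(seed=5))


@pytest.fixture(scope="session")
def full_summaries(full_campaign):
    return summarize_campaign(process_records(full_campaign))
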