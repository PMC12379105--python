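import pytest

from fieldflux.fluxqc import process_campaign
from fieldflux.synthetic import FluxDistribution, generate_diurnal_campaign

#: Injection rates for the failure-mode campaign used across tests.
FAILURE_WEIGHTS = {
    "high_start": 0.08,
    "low_start": 0.08,
    "nonmonotone_noise": 0.08,
    "negative_er_slope": 0.08,
    "b_artefact": 0.08,
}


@pytest.fixture(scope="session")
def noise_free_campaign():
    """One site, 12 hourly rounds, all failure modes injected, zero noise."""
    dist = FluxDistribution(noise_sd=0.0, failure_weights=FAILURE_WEIGHTS)
    return generate_diurnal_campaign(
        n_sites=1, n_rounds=12, scenarios=dist, missing_rounds=[5], seed=20220723
    )


@pytest.fixture(scope="session")
def processed_campaign(noise_free_campaign):
    """The same campaign run through the full flux pipeline."""
    records = process_campaign(
        noise_free_campaign.series, schedule=noise_free_campaign.schedule
    )
    return noise_free_campaign, records
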