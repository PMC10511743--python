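import pytest

from wetviro.synth import ScenarioConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    return ScenarioConfig(n_votus=60, n_mags=12, n_sip_votus=8, n_sip_mags=4, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config() -> ScenarioConfig:
    """Zero-noise scenario for exact truth recovery."""
    return ScenarioConfig(
        n_votus=40,
        n_mags=8,
        n_sip_votus=6,
        n_sip_mags=3,
        abundance_cv=0.0,
        density_sd=0.0,
        sip_weight_cv=0.0,
        seed=23,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)
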