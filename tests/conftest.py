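import pytest

from sangerhts import SimulationConfig, anchors_from_panel, generate_otu_panel


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(rng_seed=1)


@pytest.fixture(scope="session")
def panel(default_config):
    return generate_otu_panel(default_config)


@pytest.fixture(scope="session")
def anchors(panel):
    return anchors_from_panel(panel)


@pytest.fixture(scope="session")
def noise_free_config():
    return SimulationConfig(chromatogram_noise_sd=0.0, rng_seed=1)
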