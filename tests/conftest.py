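import pytest

from nucleiseg import SynthConfig, generate_sample


@pytest.fixture(scope="session")
def small_synth_config():
    """Small, fast synthetic scene used across tests."""
    return SynthConfig(image_height=128, image_width=128,
                       n_nuclei_range=(4, 6), radius_range=(6, 10), seed=11)


@pytest.fixture(scope="session")
def sample_pair(small_synth_config):
    return generate_sample(small_synth_config, 0)


@pytest.fixture(scope="session")
def default_sample():
    """One 256x256 sample at the default study conditions."""
    return generate_sample(SynthConfig(seed=3), 0)


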