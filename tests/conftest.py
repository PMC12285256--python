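import pytest

from dropscreen import simulate as sim


@pytest.fixture(scope="session")
def spec_clean():
    """Noise-free default imaging scenario."""
    return sim.default_image_spec(noise_sd=0.0)


@pytest.fixture(scope="session")
def spec_noisy():
    """Default imaging scenario with its configured acquisition noise."""
    return sim.default_image_spec()


@pytest.fixture(scope="session")
def strains():
    return sim.model_strains()
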