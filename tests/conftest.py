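import pytest

from abarddm.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small but complete synthetic dataset bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    config = SimulationConfig(seed=11, n_genes=40)
    return simulate_dataset(config, outdir)


@pytest.fixture(scope="session")
def noiseless_bundle(tmp_path_factory):
    """A bundle whose DE statistics carry no noise, so group classification
    must recover the truth table exactly."""
    outdir = tmp_path_factory.mktemp("bundle_noiseless")
    config = SimulationConfig(seed=5, n_genes=120, de_noise_sd=0.0)
    return simulate_dataset(config, outdir)
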