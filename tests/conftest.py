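import numpy as np
import pytest

from mirreg.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def bundle():
    """One default simulated bundle shared across the suite (seed 7)."""
    return simulate_bundle(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The same bundle written to disk in the interchange formats."""
    from mirreg.pipeline import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
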