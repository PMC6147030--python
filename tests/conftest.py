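import numpy as np
import pytest

from endoscan.synthetic import SimConfig, SimResult, run_simulation


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> tuple[SimResult, "pathlib.Path"]:
    """A small simulated input set shared across tests (seed fixed)."""
    out = tmp_path_factory.mktemp("simdata")
    config = SimConfig(seed=11, n_native=150, n_alien=15)
    sim = run_simulation(config, out)
    return sim, out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
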