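import numpy as np
import pytest

from boltscan import cli_io, poolcalls, simcross


def small_sim_config(seed: int = 7, **overrides) -> simcross.CrossSimConfig:
    """A fast configuration: one 1-Mb scaffold plus a 0.5-Mb unlinked one."""
    defaults = dict(
        scaffolds=(("scA", 1_000_000), ("scB", 500_000)),
        snp_density=2e-4,
        causal=("scA", 500_000),
        n_f2=200,
        n_b_pool=120,
        crossover_lambda_per_bp=1e-6,
        seed=seed,
    )
    defaults.update(overrides)
    return simcross.CrossSimConfig(**defaults)


@pytest.fixture(scope="session")
def desk_dataset() -> simcross.SimulatedDataset:
    """One default-condition desk-scale run, shared across tests."""
    return simcross.simulate_dataset(simcross.CrossSimConfig(seed=11))


@pytest.fixture(scope="session")
def desk_calls(desk_dataset):
    return poolcalls.filter_candidates(cli_io.to_pooled_sites(desk_dataset))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
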