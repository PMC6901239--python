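import numpy as np
import pytest

from isodrift.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def dataset_small():
    """One small founder-effect dataset shared across read-only tests."""
    cfg = SimConfig(
        n_sites=6000, genome_length=6_000_000, n_iso=50, n_cosmo=200,
        panel_diploids=4000, N_cosmo=8000, N_iso=800, bottleneck_size=120,
        bottleneck_generations=10, g_split=60, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
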