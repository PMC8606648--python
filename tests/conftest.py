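import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """A small strong-pattern benchmark shared across tests."""
    from schybridnmf import SimulationConfig, make_benchmark, normalize_expression

    ds = make_benchmark(
        SimulationConfig(
            n_cells=120, n_genes=60, k=3, sigma=0.3, pattern="strong",
            noise_fraction=0.2, seed=7,
        )
    )
    A = normalize_expression(ds.counts, ds.cell_ids)
    return ds, A


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
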