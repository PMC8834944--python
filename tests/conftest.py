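import numpy as np
import pytest

from outletrisk import SharedComponentCAR, SyntheticConfig, generate_areal_dataset
from outletrisk.prep import decile_matrix, expected_counts


@pytest.fixture(scope="session")
def small_dataset():
    """10x10 lattice simulated from the generative model (moderate signal)."""
    cfg = SyntheticConfig(lattice_rows=10, lattice_cols=10, seed=42)
    ds = generate_areal_dataset(cfg)
    q = decile_matrix(ds.block_groups)
    ec = expected_counts(ds.block_groups)
    y = ds.block_groups[["n_tro", "n_aro", "n_taro"]].to_numpy(float)
    return ds, q, y, ec


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short two-chain fit on the 10x10 dataset, shared across tests."""
    ds, q, y, ec = small_dataset
    model = SharedComponentCAR(n_iter=3000, n_burnin=1500, n_chains=2, seed=7).fit(
        q, y, ec.E, ds.adjacency
    )
    return ds, q, y, ec, model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
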