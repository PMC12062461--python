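import numpy as np
import pytest

from miner.simulate import simulate_clusters, simulate_grn


@pytest.fixture(scope="session")
def cluster_fixture():
    """Strongly separated 3-cluster droplet-like counts (900 x 500)."""
    return simulate_clusters(n_cells=900, n_genes=500, k=3, de_fraction=0.2,
                             effect_size=2.0, seed=11)


@pytest.fixture(scope="session")
def grn_fixture():
    """Planted signed network: 10 hubs x 20 targets over 500 samples."""
    return simulate_grn(n_hubs=10, targets_per_hub=20, n_cells=500, seed=3)


@pytest.fixture(scope="session")
def hidden_driver_fixture():
    return simulate_grn(n_hubs=10, targets_per_hub=20, n_cells=500, seed=5,
                        hidden_driver=True)


@pytest.fixture(scope="session")
def blob_embedding():
    """Two well-separated Gaussian blobs in 5 dimensions, with labels."""
    rng = np.random.default_rng(0)
    a = rng.normal(0.0, 0.3, size=(60, 5))
    b = rng.normal(4.0, 0.3, size=(60, 5))
    return np.vstack([a, b]), np.repeat([0, 1], 60)
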