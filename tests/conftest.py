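import numpy as np
import pytest

from ccinet.core import MultilayerNetwork
from ccinet.synthetic import generate_sbm_multilayer


@pytest.fixture(scope="session")
def small_random_net() -> MultilayerNetwork:
    """A small dense-ish random multilayer network for structural tests."""
    rng = np.random.default_rng(42)
    inc = (rng.random((6, 40, 3)) < 0.3).astype(np.int8)
    return MultilayerNetwork(
        chaperone_ids=[f"h{i}" for i in range(6)],
        client_ids=[f"p{j:02d}" for j in range(40)],
        layer_ids=["A", "B", "C"],
        incidence=inc,
    )


@pytest.fixture(scope="session")
def planted_net():
    """Planted two-group multilayer network plus its ground truth."""
    net, truth = generate_sbm_multilayer(
        n_chaperones=15, n_clients=300, n_layers=6, K=2, affinity_contrast=10.0, seed=101
    )
    return net, truth


def make_net(incidence, layer_ids=None) -> MultilayerNetwork:
    """Build a network with auto-generated identifiers from an incidence array."""
    incidence = np.asarray(incidence)
    if incidence.ndim == 2:
        incidence = incidence[:, :, None]
    n_c, n_p, n_l = incidence.shape
    return MultilayerNetwork(
        chaperone_ids=[f"h{i}" for i in range(n_c)],
        client_ids=[f"p{j:03d}" for j in range(n_p)],
        layer_ids=layer_ids or [f"L{a}" for a in range(n_l)],
        incidence=incidence.astype(np.int8),
    )
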