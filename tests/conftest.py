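import numpy as np
import pytest

from spagic.graph import build_knn_graph
from spagic.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_bundle():
    """Tiny labelled slice: 8x8 lattice, 3 layers, 40 genes."""
    return simulate(
        SimConfig(n_domains=3, grid=(8, 8), n_genes=40, markers_per_domain=8, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_graph():
    """6 random spots, k=2: every spot has neighbors and non-neighbors."""
    coords = np.random.default_rng(42).normal(size=(6, 2)) * 3
    return build_knn_graph(coords, k=2)


@pytest.fixture(scope="session")
def default_bundle():
    """The reference study conditions: 20x20 lattice, 5 layers, 120 genes."""
    return simulate(SimConfig(seed=0))
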