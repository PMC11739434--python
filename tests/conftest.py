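import numpy as np
import pytest

import spatialfuse as sf


@pytest.fixture(scope="session")
def small_benchmark():
    """A small synthetic section (150 cells, 40 genes, 4 domains) shared by
    tests that only need consistent shapes and ground truth."""
    cfg = sf.SyntheticConfig(
        n_cells=150, n_genes=40, k_domains=4, markers_per_domain=6,
        image_side=200, seed=7,
    )
    dataset, image, truth = sf.generate_benchmark(cfg)
    return cfg, dataset, image, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_graph():
    """Seven cells with a mixed-degree radius graph, used by attention tests."""
    coords = np.random.default_rng(0).uniform(0, 10, (7, 2))
    return sf.build_radius_graph(coords, 4.0)
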