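import numpy as np
import pytest

from spatialcontrast import (
    FixtureSpec,
    SpatialDataset,
    build_knn_graph,
    simulate_domain_slide,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_dataset():
    """3 spots x 2 genes with simple coordinates."""
    return SpatialDataset(
        counts=np.array([[1.0, 2.0], [3.0, 0.0], [0.0, 5.0]]),
        gene_ids=["gA", "gB"],
        spot_ids=["s1", "s2", "s3"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def small_slide():
    """16 x 16 four-domain slide used by several training tests."""
    return simulate_domain_slide(FixtureSpec(grid=(16, 16), seed=1))


@pytest.fixture(scope="session")
def small_graph(small_slide):
    return build_knn_graph(small_slide.coords, k=3)
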