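import numpy as np
import pytest

from leafwood import SyntheticTreeSpec, generate_tree

# Desk-scale tree for unit tests: ~4.5k points, seconds to process.
SMALL_SPEC = SyntheticTreeSpec(
    trunk_height=4.0,
    trunk_radius=0.1,
    n_branches=8,
    branch_length_range=(0.8, 1.6),
    branch_radius=0.02,
    n_leaf_clusters=8,
    leaf_cluster_radius=0.25,
    points_per_unit_area_wood=700.0,
    points_per_cluster_leaf=250,
    jitter_sd=0.005,
    seed=123,
)


@pytest.fixture(scope="session")
def small_tree():
    return generate_tree(SMALL_SPEC)


@pytest.fixture(scope="session")
def benchmark_tree():
    """Default-sized tree (~27k points) for pipeline-level checks."""
    return generate_tree(SyntheticTreeSpec(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
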