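import pytest
from shapely.geometry import box

import scsm


@pytest.fixture(scope="session")
def grid3x3():
    return scsm.AdjacencyStructure.grid(3, 3)


@pytest.fixture(scope="session")
def square_grid_polygons():
    """2x2 unit squares sharing edges/corners, keyed by area_id."""
    return {
        "a00": box(0, 0, 1, 1),
        "a01": box(1, 0, 2, 1),
        "a10": box(0, 1, 1, 2),
        "a11": box(1, 1, 2, 2),
    }


@pytest.fixture(scope="session")
def four_cycle():
    """A 4-node cycle graph (the rook-contiguity 2x2 grid)."""
    return scsm.AdjacencyStructure.grid(2, 2, rule="rook")


@pytest.fixture(scope="session")
def small_dataset():
    """An 8x8 lattice dataset simulated from the generative model."""
    cfg = scsm.SyntheticConfig(nrows=8, ncols=8, seed=7)
    return scsm.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def fitted_samples(small_dataset):
    """A short but converged-ish fit of the 8x8 dataset, reused by
    posterior-analysis tests."""
    cfg = scsm.SamplerConfig(n_chains=2, burn_in=3000, retained=3000, thin=30,
                             seed=123)
    return scsm.run_chains(small_dataset.areas, small_dataset.adjacency,
                           scsm.PriorSpec(), cfg)
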