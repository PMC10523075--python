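import numpy as np
import pytest

import caprimorph as cm
from caprimorph.morphodata import join_metadata
from caprimorph.simulate import SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def template_and_sliders():
    return cm.make_template()


@pytest.fixture(scope="session")
def small_dataset():
    """A small four-group synthetic dataset shared across tests."""
    params = SimulationParams(n_per_group=(60, 40, 20, 18), seed=1234)
    configs, meta, slider_map = simulate_dataset(params)
    return join_metadata(configs, meta), slider_map, params


@pytest.fixture(scope="session")
def aligned_small(small_dataset):
    dataset, slider_map, _ = small_dataset
    return cm.align_gpa(dataset, slider_map=slider_map)


def random_configuration(rng, k=8, scale=1.0):
    """A random non-degenerate k-point configuration."""
    return rng.normal(size=(k, 2)) * scale


def random_similarity(rng, coords):
    """Apply a random rotation + translation + positive scaling."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    return coords @ rot * rng.uniform(0.3, 3.0) + rng.uniform(-20, 20, size=2)
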