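import numpy as np
import pytest

from tomopick.io import ParticleSet, Tomogram


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_tomogram(rng):
    return Tomogram(rng.normal(size=(16, 16, 16)).astype(np.float32), voxel_size=2.0)


@pytest.fixture()
def particle_set():
    centers = np.array([[4.0, 5.0, 6.0], [10.0, 3.0, 12.0], [2.5, 8.25, 1.75]])
    return ParticleSet.from_arrays(centers, [1, 2, 1], scores=[0.9, 0.5, 0.7])
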