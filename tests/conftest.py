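import numpy as np
import pytest

from bonesup import phantom, projection


@pytest.fixture(scope="session")
def small_population():
    """Population ranges on a 48-cubed grid: fast to rasterize, same anatomy."""
    return phantom.default_population((48, 48, 48), 0.03)


@pytest.fixture(scope="session")
def small_pair(small_population):
    params = phantom.sample_phantom_params(small_population, seed=3)
    return phantom.build_phantom_pair(params)


@pytest.fixture(scope="session")
def small_pair_images(small_pair):
    """Jointly-normalized 8-bit with/without-bone projections at 45 degrees."""
    geom = projection.ProjectionGeometry(45.0)
    raw_w = projection.project_drr(small_pair.with_bone, geom)
    raw_wo = projection.project_drr(small_pair.without_bone, geom)
    return projection.normalize_pair(raw_w, raw_wo)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
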