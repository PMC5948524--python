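import numpy as np
import pytest

import olivescan as ov


@pytest.fixture(scope="session")
def small_scene():
    """Short, sparse hedgerow used by fast unit tests (2 trees, low density)."""
    cfg = ov.SceneConfig(transect_length=4.0, tree_spacing=1.35,
                         crown_point_density=800.0, ground_point_density=20.0,
                         seed=11)
    return ov.generate_hedgerow(cfg)


@pytest.fixture(scope="session")
def default_scene():
    """Full-length transect at the default study conditions."""
    return ov.generate_hedgerow(ov.SceneConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(202401)


def make_cloud(points, **meta):
    return ov.PointCloud(np.asarray(points, dtype=float), **meta)
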