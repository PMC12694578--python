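import numpy as np
import pytest

from voxsal.model import ArchitectureSpec, build_model
from voxsal.synthetic import make_atlas


@pytest.fixture(scope="session")
def small_atlas():
    """8-area, 4-network phantom atlas on a 16-cubed grid."""
    return make_atlas(n_areas=8, grid_shape=(16, 16, 16), n_networks=4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_model():
    """Smallest classifier with a residual stage: 4-cubed, 2-channel features."""
    spec = ArchitectureSpec(
        stem_channels=2,
        stem_kernel=3,
        stem_stride=1,
        stem_pool=False,
        stages=((1, 2),),
        stage_strides=(1,),
        dropout=0.0,
    )
    return build_model(spec, seed=3)
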