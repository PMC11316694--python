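import numpy as np
import pytest

from adiposeg.phantom import PhantomSpec


@pytest.fixture
def small_spec():
    """Coarse, fast phantom: same torso geometry on a 48x48x10 grid."""
    return PhantomSpec(matrix_size=(48, 48, 10), voxel_size_mm=(8.0, 8.0, 10.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
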