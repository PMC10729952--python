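import numpy as np
import pytest

from cgdesign.model import CgnnModel, ModelConfig
from cgdesign.synthetic import SyntheticSpec, label_sequence, make_backbone


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a translation."""
    from scipy.spatial.transform import Rotation
    R = Rotation.random(random_state=int(rng.integers(2 ** 31))).as_matrix()
    t = rng.normal(0.0, 10.0, size=3)
    return R, t


@pytest.fixture(scope="session")
def helix12():
    return make_backbone(SyntheticSpec(segments=[("helix", 12)]))


@pytest.fixture(scope="session")
def mixed_structure():
    """A 30-residue helix/strand/coil backbone with labeled sequence."""
    spec = SyntheticSpec(
        segments=[("helix", 12), ("coil", 6), ("strand", 12)], seed=11)
    s = make_backbone(spec)
    s.native_seq = label_sequence(s)
    return s


@pytest.fixture(scope="session")
def small_model():
    return CgnnModel(ModelConfig(width=32, blocks=2, dropout=0.0, seed=5))
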