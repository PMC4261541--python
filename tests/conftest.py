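import numpy as np
import pytest

from tcrdock import ToyComplexSpec, make_toy_complex
from tcrdock.geometry import RigidTransform
from scipy.spatial.transform import Rotation


@pytest.fixture(scope="session")
def toy_case():
    """Noise-free toy case with the default planted pose (seed 0)."""
    return make_toy_complex(ToyComplexSpec(seed=0))


@pytest.fixture(scope="session")
def noisy_case():
    return make_toy_complex(ToyComplexSpec(seed=1, noise_sigma=0.3))


def random_rigid(seed: int) -> RigidTransform:
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
    return RigidTransform(R, rng.uniform(-30, 30, 3))
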