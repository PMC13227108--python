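import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.transform import Rotation

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


def random_frame(rng):
    """A random valid frame: scipy Rotation is the independent source of
    orthonormal triads (rows = frame axes)."""
    from dnaforge.geometry import Frame

    triad = Rotation.random(random_state=rng).as_matrix().T
    return Frame(rng.normal(scale=3.0, size=3), triad)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def linear80():
    import dnaforge as df

    return df.make(n_bp=80, sequence_seed=1)


@pytest.fixture(scope="session")
def small_duplex():
    import dnaforge as df

    return df.make(sequence="ACGTTGCAAC")
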