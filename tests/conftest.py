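import numpy as np
import pytest

from morphorad.imageio import Volume
from morphorad.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Clean default-resolution phantom and its label map (session-cached)."""
    spec = PhantomSpec()
    vol, lab = make_phantom(spec)
    return spec, vol, lab


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), units="arbitrary"):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return Volume(data=np.asarray(data, dtype=float), affine=aff, units=units)
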