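import numpy as np
import pytest

from ventrimetry.dti import color_encode, compute_fa_e1
from ventrimetry.simulate import PhantomSpec, make_phantom, spec_for_ventriculomegaly

# Small-but-accurate phantom scale used throughout the suite; angles and
# ratios are scale-invariant, so this only trades voxel count for speed.
TEST_SCALE = 0.75
FAST_SCALE = 0.6


@pytest.fixture(scope="session")
def hc_phantom():
    """Healthy-control-like phantom (v=1, SA=75.7 deg)."""
    return make_phantom(spec_for_ventriculomegaly(1.0, scale=TEST_SCALE), seed=0)


@pytest.fixture(scope="session")
def nph_phantom():
    """NPH-like phantom: dilated ventricles, narrow SA of 25 deg."""
    spec = PhantomSpec(ventriculomegaly=2.0, true_sa=25.0, scale=TEST_SCALE)
    return make_phantom(spec, seed=0)


@pytest.fixture(scope="session")
def hc_cfa(hc_phantom):
    return color_encode(compute_fa_e1(hc_phantom.tensor))


@pytest.fixture(scope="session")
def nph_cfa(nph_phantom):
    return color_encode(compute_fa_e1(nph_phantom.tensor))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
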