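import numpy as np
import pytest
from hypothesis import settings

from blendspec import SpectraBlock

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_block(values, wavelengths=None, tag="VisNIR", ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if wavelengths is None:
        wavelengths = np.linspace(460.0, 1020.0, p)
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    return SpectraBlock(values, wavelengths, ids, tag)


@pytest.fixture
def random_block(rng):
    """20 smooth-ish random spectra over a uniform 50-point grid."""
    lam = np.linspace(500.0, 900.0, 50)
    base = 0.3 + 0.4 / (1 + np.exp(-(lam - 700) / 50))
    values = base + 0.05 * rng.standard_normal((20, 50)).cumsum(axis=1) / 7
    return make_block(values, lam)
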