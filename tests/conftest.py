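import numpy as np
import pytest

from dendrhythm.cell import assemble_cell
from dendrhythm.morphology import MorphologyParams, build_synthetic_morphology


@pytest.fixture(scope="session")
def small_morph():
    """Reduced morphology used for desk-scale simulations."""
    return build_synthetic_morphology(MorphologyParams(scale=0.3), seed=1)


@pytest.fixture(scope="session")
def small_cell(small_morph):
    return assemble_cell(small_morph)


@pytest.fixture(scope="session")
def full_morph():
    return build_synthetic_morphology()


def count_aps(v, dt, t0=0.0, t1=np.inf, thresh=-10.0):
    v = np.asarray(v)
    up = np.nonzero((v[1:] >= thresh) & (v[:-1] < thresh))[0] + 1
    t = dt * up
    return int(np.sum((t >= t0) & (t < t1)))
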