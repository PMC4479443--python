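import logging

import numpy as np
import pytest
from skimage.draw import disk

# stage-internal warnings (variance floors etc.) are expected on synthetic data
logging.getLogger("leukosmear").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_smear():
    """One deterministic default smear with its ground truth."""
    from leukosmear.synthetic import SmearSpec, generate_smear

    return generate_smear(SmearSpec(seed=7))


@pytest.fixture(scope="session")
def overlap_smear():
    """A smear where every leukocyte pair overlaps."""
    from leukosmear.synthetic import SmearSpec, generate_smear

    return generate_smear(SmearSpec(n_leukocytes=4, overlap_fraction=0.5, seed=11))


def disc_mask(shape, center, radius):
    m = np.zeros(shape, dtype=bool)
    rr, cc = disk(center, radius, shape=shape)
    m[rr, cc] = True
    return m


def fused_discs(centers, radius=20, shape=(100, 160)):
    m = np.zeros(shape, dtype=bool)
    for c in centers:
        m |= disc_mask(shape, c, radius)
    return m


@pytest.fixture
def two_disc_mask():
    return fused_discs([(50, 40), (50, 70)], radius=20, shape=(100, 120))


@pytest.fixture
def three_disc_mask():
    return fused_discs([(50, 40), (50, 70), (50, 100)], radius=20, shape=(100, 160))
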