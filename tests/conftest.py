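import numpy as np
import pytest

from videoaf.model import ScanConditions
from videoaf.scenes import SyntheticSceneSpec, make_synthetic_source
from videoaf.simulate import FocalTimeScan


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_patch(rng):
    """Seeded random 32x32 patch in [0, 1]."""
    return rng.random((32, 32))


@pytest.fixture
def textured_frame():
    """Deterministic 64x64 textured in-focus frame."""
    src = make_synthetic_source(SyntheticSceneSpec("blobs", 1.0, 7), (64, 64), 1)
    return src.frame_at(0)


@pytest.fixture
def tiny_scan():
    """Short synthetic focal-time scan under default study conditions."""
    return ScanConditions(episode_len=30).scan(5)


@pytest.fixture
def frozen_scan():
    """Scan with frozen optimal focal power 0.45 and fixed blur gain."""
    src = make_synthetic_source(SyntheticSceneSpec("filtered-noise", 1.0, 3), (64, 64), 30)
    return FocalTimeScan(src, seed=3, fstar_walk_std=0.0, sigma0=5.0, fstar0=0.45)
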