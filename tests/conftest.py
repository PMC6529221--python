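import numpy as np
import pytest

from lhoverlap.volumes import BinaryMask, LabelVolume


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def small_volume(rng):
    return LabelVolume(rng.normal(50, 10, size=(12, 10, 8)).astype(np.float32))


def make_mask(data, **meta):
    meta.setdefault("cell_type", "test")
    return BinaryMask(np.asarray(data, dtype=bool), **meta)


@pytest.fixture
def mask_factory():
    return make_mask
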