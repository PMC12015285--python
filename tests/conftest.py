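import numpy as np
import pytest

from leukosuite import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smear_sample():
    """One clean lymphocyte-like smear with ground truth."""
    return synth.render_smear(synth.DEFAULT_CLASSES[0], size=(96, 96), seed=42)


@pytest.fixture
def random_mask_pairs(rng):
    """100 random 12x12 binary mask pairs (both nonempty)."""
    pairs = []
    while len(pairs) < 100:
        a = rng.random((12, 12)) < 0.4
        b = rng.random((12, 12)) < 0.4
        if a.any() and b.any():
            pairs.append((a, b))
    return pairs
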