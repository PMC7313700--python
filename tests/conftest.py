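import numpy as np
import pytest


def random_image_pair(seed: int, shape=(16, 16), p_lesion=0.4):
    """Random RGB image + nonempty random binary mask of the same shape."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, size=shape + (3,), dtype=np.uint8)
    mask = (rng.random(shape) < p_lesion).astype(np.uint8)
    if not mask.any():
        mask[shape[0] // 2, shape[1] // 2] = 1
    return img, mask


@pytest.fixture
def image_pair_factory():
    return random_image_pair
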