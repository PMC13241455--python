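import numpy as np
import pytest

from fatmap.mapping import FatFractionSlice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_slice(fat, mask_left, mask_right=None, cor=(0.0, 0.0), level="L4L5",
               slice_index=1, pixel_spacing=1.0, subject="S0000"):
    masks = {"left": mask_left}
    if mask_right is not None:
        masks["right"] = mask_right
    return FatFractionSlice(fat=fat, masks=masks, cor=cor, level=level,
                            slice_index=slice_index, pixel_spacing=pixel_spacing,
                            subject=subject)


@pytest.fixture
def random_masked_slice(rng):
    """A 20x20 slice with an irregular random mask away from the CoR."""
    def _make(seed=None, shape=(20, 20), cor=(2.0, 2.0)):
        r = np.random.default_rng(seed) if seed is not None else rng
        mask = np.zeros(shape, dtype=bool)
        while mask.sum() < 30:
            mask |= r.random(shape) < 0.25
            mask[: int(cor[0]) + 1, : int(cor[1]) + 1] = False
        fat = np.clip(r.normal(30, 10, shape), 0, 100)
        return make_slice(fat, mask, cor=cor)

    return _make
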