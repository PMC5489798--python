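import numpy as np
import pytest

from vesselcal import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tube_phantom():
    """Noise-free horizontal tube, width 8, with its ground truth."""
    return generate_phantom(PhantomSpec(width_px=8.0, orientation_deg=0.0))


@pytest.fixture
def blob_masks(rng):
    """Random smooth binary blobs for thinning/tracing property tests."""
    masks = []
    for _ in range(20):
        from scipy import ndimage
        f = ndimage.gaussian_filter(rng.normal(size=(64, 64)), 3.0)
        masks.append((f > np.quantile(f, 0.7)).astype(np.uint8))
    return masks
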