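import numpy as np
import pytest

from mucoscape import masks, phantom

DENSE_LUMEN = 4.0e11  # per ml; saturates the luminal field at 0.5 um/px


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    return (a & b).sum() / union if union else 1.0


def make_flat_spec(**overrides) -> phantom.PhantomSpec:
    kwargs = dict(
        image_height_px=256,
        image_width_px=256,
        pixel_size_um=0.5,
        inner_mucus_thickness_um=30.0,
        bacterial_density_per_ml=DENSE_LUMEN,
        seed=0,
    )
    kwargs.update(overrides)
    return phantom.PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def flat_phantom():
    """A standard dense-lumen flat phantom shared across read-only tests."""
    spec = make_flat_spec(seed=11)
    img, truth = phantom.generate_phantom(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def segmented_flat_phantom(flat_phantom):
    spec, img, truth = flat_phantom
    params = masks.SegmentationParams()
    muc = masks.mucosal_mask(img, params)
    lum = masks.luminal_mask(img, muc, params)
    return spec, img, truth, muc, lum
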