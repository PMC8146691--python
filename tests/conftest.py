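import numpy as np
import pytest

from localrad import PipelineConfig, RoiImageStack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Window of 5 px at unit spacing; cheap to brute-force."""
    return PipelineConfig(tissue_unit_mm=5.0, local_entropy_bins=16)


def make_stack(images, masks=None, spacing=1.0, patient_id="p0"):
    """Build a stack from arrays; full-ROI masks by default."""
    if masks is None:
        masks = [np.ones_like(img, dtype=bool) for img in images]
    return RoiImageStack(
        patient_id=patient_id,
        slices=list(images),
        masks=list(masks),
        pixel_spacing_mm=spacing,
    )


@pytest.fixture
def random_stack(rng):
    """One 24x24 integer-valued slice, fully masked (integer values make
    shift/scale transformations float-exact)."""
    img = rng.integers(0, 256, (24, 24)).astype(np.float64)
    return make_stack([img])
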