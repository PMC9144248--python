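import numpy as np
import pytest

from miunet.phantom import (
    AnatomyModel,
    GeometryRanges,
    generate_pairs,
    lge_preset,
    render_pair,
    sample_anatomy,
    ssfp_preset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def anatomy64():
    return sample_anatomy(GeometryRanges().scaled(64), seed=7)


@pytest.fixture
def pair64(anatomy64):
    return render_pair(anatomy64, ssfp_preset(), lge_preset(), seed=3)


@pytest.fixture(scope="session")
def phantom_set64():
    """Small in-memory phantom dataset shared by training-level tests."""
    return generate_pairs(12, GeometryRanges().scaled(64), seed=11)


@pytest.fixture(scope="session")
def clean_anatomy():
    """Hand-built anatomy with no patches, centered, for exact render checks."""
    return AnatomyModel(
        image_size=64,
        lv_center=(31.5, 31.5),
        lvc_radius=10.0,
        wall_thickness_base=4.0,
        septal_thickening_factor=1.5,
        rv_crescent=(2.0, 6.0),
        enhancement_patches=(),
    )
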