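import numpy as np
import pytest

from cvitools import BoundarySet, BScanImage


def flat_boundaries(width=512, ilm=20.0, rpe_inner=100.0, rpe_outer=108.0, csj=200.0,
                    fovea_x=None, **kw):
    return BoundarySet(
        boundaries={
            "ILM": np.full(width, ilm, dtype=float),
            "RPE_inner": np.full(width, rpe_inner, dtype=float),
            "RPE_outer": np.full(width, rpe_outer, dtype=float),
            "CSJ": np.full(width, csj, dtype=float),
        },
        fovea_x=fovea_x,
        **kw,
    )


def gray_image(height=256, width=512, value=128, lateral=10.0, axial=5.0, bit_depth=8):
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    px = np.full((height, width), value, dtype=dtype)
    return BScanImage(px, bit_depth, lateral, axial)


@pytest.fixture
def flat_setup():
    """Flat-boundary scene used across geometry/metrics tests."""
    img = gray_image()
    bnd = flat_boundaries(width=img.width)
    return img, bnd
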