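import numpy as np
import pytest

from octaquant import AnnulusSpec, EnFaceImage, ScanGeometry, make_annulus_mask


@pytest.fixture(scope="session")
def geometry() -> ScanGeometry:
    """Design-eye geometry: 3 mm nominal field, 245 px, unit magnification."""
    return ScanGeometry(axial_length_mm=24.46)


@pytest.fixture(scope="session")
def annulus(geometry):
    return make_annulus_mask(AnnulusSpec(), geometry)


@pytest.fixture
def bar_image(geometry) -> tuple[EnFaceImage, np.ndarray]:
    """SCP-slab image with one straight bright horizontal bar (width 6 px)
    on a flat background, plus the planted bar mask."""
    n = geometry.n_pixels_per_side
    pixels = np.full((n, n), 30, dtype=np.uint8)
    bar = np.zeros((n, n), dtype=bool)
    bar[120:126, :] = True
    pixels[bar] = 220
    return EnFaceImage(pixels=pixels, slab="SCP", geometry=geometry), bar
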