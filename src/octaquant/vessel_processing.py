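"""Vessel enhancement, binarization and masking for en-face OCTA slabs.

The processing chain mirrors the standard en-face quantification recipe:

1. large-vessel (LV) contrast enhancement in the superficial plexus with a
   Gabor orientation bank combined with a multi-scale Hessian tubularity
   filter;
2. LV segmentation by quantile thresholding of the combined response;
3. vessel binarization of the retinal slabs at the mean image intensity;
4. masking of the manually annotated FAZ;
5. exclusion of LV projection artifacts from the choriocapillaris slab;
6. flow-deficit binarization of the choriocapillaris one standard deviation
   below the mean.

Threshold conventions are fixed and documented: vessels use ``>= mean``
(a constant image is all vessel), flow deficits use ``< mean - sd`` with the
population (divisor N) standard deviation (a constant image has no
deficits). Both rules are invariant under positive affine intensity
transforms. Image statistics for vessel binarization use the full image;
choriocapillaris statistics exclude artifact pixels so LV shadows do not
bias the mean and SD downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import filters, morphology

import shapely

from .errors import ConfigError, DegenerateInputError, ValidationError
from .image_io import BinaryMap, EnFaceImage, FAZAnnotation
from .scaling import ScanGeometry


@dataclass
class VesselnessParams:
    """Filter-bank parameters for large-vessel enhancement.

    Wavelength is in pixels and defaults to the calibre of superficial
    arterioles/venules at ~12.2 um/px sampling; 12 orientations give 15
    degree steps; Hessian tubularity runs at sigma = 2, 3, 4 px.
    """

    gabor_wavelength_px: float = 8.0
    n_orientations: int = 12
    gabor_bandwidth: float = 1.0
    hessian_scales_px: Sequence[float] = (2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.n_orientations < 1:
            raise ConfigError("n_orientations must be >= 1")
        if not self.hessian_scales_px:
            raise ConfigError("hessian_scales_px must be non-empty")
        if self.gabor_wavelength_px <= 0:
            raise ConfigError("gabor_wavelength_px must be positive")


@dataclass
class VesselnessResponse:
    """Non-negative vesselness response with the parameters that produced it."""

    response: np.ndarray
    params: VesselnessParams

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        if (self.response < 0).any():
            raise ValidationError("vesselness response must be non-negative")


def _minmax(arr: np.ndarray, guard: float = 1e-12) -> np.ndarray:
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < guard:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def enhance_large_vessels(
    img: EnFaceImage, params: VesselnessParams | None = None
) -> VesselnessResponse:
    """Combined Gabor/Hessian large-vessel contrast enhancement (SCP only).

    The response is the pixelwise maximum of (a) the max-over-orientations
    Gabor magnitude and (b) the max-over-scales Sato tubularity measure,
    each min-max normalized to [0, 1] before combination. A structureless
    (constant) image yields an identically zero response.
    """
    if img.slab != "SCP":
        raise ValidationError(f"large-vessel enhancement expects the SCP slab, got {img.slab}")
    params = params or VesselnessParams()
    pixels = np.asarray(img.pixels, dtype=float) / 255.0

    freq = 1.0 / params.gabor_wavelength_px
    gabor_max = np.zeros_like(pixels)
    for k in range(params.n_orientations):
        theta = np.pi * k / params.n_orientations
        real, imag = filters.gabor(
            pixels, frequency=freq, theta=theta, bandwidth=params.gabor_bandwidth
        )
        np.maximum(gabor_max, np.hypot(real, imag), out=gabor_max)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sato warns on flat images
        hessian = filters.sato(
            pixels, sigmas=list(params.hessian_scales_px), black_ridges=False
        )

    combined = np.maximum(_minmax(gabor_max), _minmax(hessian))
    return VesselnessResponse(response=combined, params=params)


def segment_large_vessels(
    resp: VesselnessResponse,
    quantile: float = 0.92,
    min_size_px: int = 50,
    close_radius_px: int = 1,
) -> BinaryMap:
    """Threshold the vesselness response at a quantile, drop small components,
    and close with a disk.

    Thresholding is strict (``> quantile value``) so an identically zero
    response yields an empty mask, and raising the quantile never adds
    pixels.
    """
    if not 0 <= quantile < 1:
        raise ConfigError(f"quantile must be in [0, 1), got {quantile}")
    r = resp.response
    raw = r > np.quantile(r, quantile)
    # keep components of at least min_size_px pixels
    mask = morphology.remove_small_objects(raw, max_size=min_size_px - 1)
    if close_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(close_radius_px))
    return BinaryMap(mask=mask, label="large_vessels", source_slab="SCP")


def binarize_vessels(img: EnFaceImage) -> BinaryMap:
    """Vessel map of a retinal slab: pixel is vessel iff intensity >= image mean.

    The mean is computed over the full image before any masking. The
    inclusive rule means a perfectly constant image is classified entirely
    as vessel; the rule is invariant under positive affine intensity maps.
    """
    if img.slab not in ("SCP", "DCP"):
        raise ValidationError(f"vessel binarization expects SCP or DCP, got {img.slab}")
    pixels = np.asarray(img.pixels, dtype=float)
    return BinaryMap(mask=pixels >= pixels.mean(), label="vessels", source_slab=img.slab)


def rasterize_polygon(
    faz: FAZAnnotation, geometry: ScanGeometry
) -> np.ndarray:
    """Boolean grid of pixels whose centers fall inside the annotation polygon."""
    x_mm, y_mm = geometry.pixel_centers_mm()
    inside = shapely.contains_xy(faz.polygon(), x_mm.ravel(), y_mm.ravel())
    return inside.reshape(x_mm.shape)


def mask_faz(
    vessels: BinaryMap, faz: FAZAnnotation, geometry: ScanGeometry
) -> BinaryMap:
    """Zero out vessel pixels whose centers fall inside the FAZ polygon.

    Idempotent; a polygon entirely outside the field triggers a warning and
    returns the mask unchanged.
    """
    expected = {"SCP": "superficial", "DCP": "deep"}
    if vessels.source_slab in expected and faz.layer != expected[vessels.source_slab]:
        raise ValidationError(
            f"FAZ layer {faz.layer!r} does not match slab {vessels.source_slab!r}"
        )
    inside = rasterize_polygon(faz, geometry)
    if not inside.any():
        warnings.warn("FAZ polygon lies entirely outside the imaged field", stacklevel=2)
        return BinaryMap(vessels.mask.copy(), vessels.label, vessels.source_slab)
    return BinaryMap(vessels.mask & ~inside, vessels.label, vessels.source_slab)


def remove_cc_artifacts(
    cc: EnFaceImage, lv_mask: BinaryMap, dilation_radius_px: int = 1
) -> tuple[EnFaceImage, BinaryMap]:
    """Artifact mask for the choriocapillaris: the SCP large-vessel mask
    dilated by a small radius.

    Artifact pixels are excluded from all downstream CC statistics and
    metrics; the image itself is returned unchanged (no inpainting).
    """
    if cc.slab != "CC":
        raise ValidationError(f"artifact removal expects the CC slab, got {cc.slab}")
    if lv_mask.mask.shape != cc.pixels.shape:
        raise ValidationError(
            f"LV mask shape {lv_mask.mask.shape} does not match CC {cc.pixels.shape}"
        )
    artifact = lv_mask.mask
    if dilation_radius_px > 0 and artifact.any():
        artifact = morphology.dilation(artifact, morphology.disk(dilation_radius_px))
    return cc, BinaryMap(mask=artifact, label="artifact", source_slab="CC")


def binarize_flow_deficits(
    cc: EnFaceImage, artifact: BinaryMap | None = None
) -> BinaryMap:
    """Flow-deficit map of the choriocapillaris: intensity < mean - SD.

    Mean and population standard deviation (divisor N) are computed over the
    non-artifact pixels. The strict ``<`` rule means a constant image (SD 0)
    has no flow deficits; the rule is equivariant under positive affine
    intensity transforms.
    """
    if cc.slab != "CC":
        raise ValidationError(f"flow-deficit binarization expects CC, got {cc.slab}")
    pixels = np.asarray(cc.pixels, dtype=float)
    keep = np.ones_like(pixels, dtype=bool) if artifact is None else ~artifact.mask
    if not keep.any():
        raise DegenerateInputError("all pixels are flagged as artifact")
    vals = pixels[keep]
    threshold = vals.mean() - vals.std(ddof=0)
    return BinaryMap(mask=keep & (pixels < threshold), label="flow_deficits", source_slab="CC")
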