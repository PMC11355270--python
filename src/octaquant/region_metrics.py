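"""Annulus construction and regional quantification of perfusion and flow.

All regional metrics are measured inside a magnification-corrected,
fovea-centered annulus (default inner diameter 1.0 mm, outer diameter
2.5 mm). A pixel belongs to the annulus iff its center lies at a distance
``inner_radius <= d < outer_radius`` from the annulus center, distances in
corrected millimetres (pixel-center rule, no area weighting).

Perfusion density (PD) is the percentage of vessel pixels per total annulus
pixels; choriocapillaris flow-deficit (FD) density is the percentage of
deficit pixels per non-artifact annulus pixels. FD components are counted
with 8-connectivity and their mean size converted to um^2 with the
corrected pixel area.

"SCP without large vessels" removes the LV mask dilated by a configurable
radius (default 3 px) from the numerator while keeping the full annulus as
denominator: the exclusion removes peri-vascular signal around the large
vessels as well, which is why the capillary PD sits well below the simple
difference between total SCP PD and LV PD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import morphology

from .errors import ConfigError, DegenerateInputError, ValidationError
from .faz_metrics import FAZMetrics, compute_faz_metrics
from .image_io import BinaryMap, EnFaceImage, FAZAnnotation
from .scaling import ScanGeometry
from . import vessel_processing as vp

#: 8-connectivity structuring element for FD component labelling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class AnnulusSpec:
    """Fovea-centered annulus of measurement, in corrected mm."""

    center_mm: tuple[float, float] = (0.0, 0.0)
    inner_diameter_mm: float = 1.0
    outer_diameter_mm: float = 2.5

    def __post_init__(self) -> None:
        # inner diameter 0 degenerates to a disk, which is allowed
        if not 0 <= self.inner_diameter_mm < self.outer_diameter_mm:
            raise ConfigError(
                f"need 0 <= inner ({self.inner_diameter_mm}) < outer "
                f"({self.outer_diameter_mm}) diameter"
            )


@dataclass(frozen=True)
class OCTAMetrics:
    """The 13 per-eye outputs: 4 perfusion densities, 2 x 3 FAZ metrics,
    3 choriocapillaris flow-deficit metrics."""

    pd_lv_pct: float
    pd_scp_pct: float
    pd_scp_wo_lv_pct: float
    pd_dcp_pct: float
    faz_superficial: FAZMetrics
    faz_deep: FAZMetrics
    fd_density_pct: float
    fd_mean_size_um2: float  # NaN when fd_count == 0
    fd_count: int

    def __post_init__(self) -> None:
        for name in ("pd_lv_pct", "pd_scp_pct", "pd_scp_wo_lv_pct", "pd_dcp_pct", "fd_density_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{name}={v} outside [0, 100]")
        if self.fd_count < 0:
            raise ValidationError("fd_count must be >= 0")

    def to_row(self) -> dict:
        """Flat dict matching the metrics CSV column names."""
        return {
            "pd_lv_pct": self.pd_lv_pct,
            "pd_scp_pct": self.pd_scp_pct,
            "pd_scp_wo_lv_pct": self.pd_scp_wo_lv_pct,
            "pd_dcp_pct": self.pd_dcp_pct,
            "faz_sup_area_mm2": self.faz_superficial.area_mm2,
            "faz_sup_perimeter_mm": self.faz_superficial.perimeter_mm,
            "faz_sup_circularity": self.faz_superficial.circularity,
            "faz_deep_area_mm2": self.faz_deep.area_mm2,
            "faz_deep_perimeter_mm": self.faz_deep.perimeter_mm,
            "faz_deep_circularity": self.faz_deep.circularity,
            "fd_density_pct": self.fd_density_pct,
            "fd_size_um2": self.fd_mean_size_um2,
            "fd_number": self.fd_count,
        }


@dataclass
class PipelineConfig:
    """Tunable parameters of the whole quantification chain."""

    annulus: AnnulusSpec = field(default_factory=AnnulusSpec)
    vesselness: vp.VesselnessParams = field(default_factory=vp.VesselnessParams)
    lv_quantile: float = 0.92
    lv_min_size_px: int = 50
    lv_close_radius_px: int = 1
    cc_artifact_dilation_px: int = 1
    lv_exclusion_dilation_px: int = 3


def make_annulus_mask(spec: AnnulusSpec, geometry: ScanGeometry) -> BinaryMap:
    """Rasterize the annulus on the corrected pixel grid (pixel-center rule)."""
    x_mm, y_mm = geometry.pixel_centers_mm()
    cx, cy = spec.center_mm
    d = np.hypot(x_mm - cx, y_mm - cy)
    outer_r = spec.outer_diameter_mm / 2.0
    half_field = geometry.actual_scan_length_mm / 2.0
    if outer_r > half_field + 1e-12:
        warnings.warn(
            f"annulus outer radius {outer_r:.3f} mm exceeds the half field "
            f"{half_field:.3f} mm; the annulus is clipped",
            stacklevel=2,
        )
    mask = (d >= spec.inner_diameter_mm / 2.0) & (d < outer_r)
    return BinaryMap(mask=mask, label="annulus")


def perfusion_density(
    vessels: BinaryMap, annulus: BinaryMap, exclude: BinaryMap | None = None
) -> float:
    """Percentage of vessel pixels per total annulus pixels.

    ``exclude`` removes pixels from numerator and denominator alike; without
    it the denominator is the full annulus.
    """
    if vessels.mask.shape != annulus.mask.shape:
        raise ValidationError("vessel and annulus masks differ in shape")
    region = annulus.mask if exclude is None else annulus.mask & ~exclude.mask
    denom = int(region.sum())
    if denom == 0:
        raise DegenerateInputError("empty measurement region")
    return 100.0 * int((vessels.mask & region).sum()) / denom


def fd_density(
    fd: BinaryMap, annulus: BinaryMap, artifact: BinaryMap | None = None
) -> float:
    """Percentage of flow-deficit pixels per non-artifact annulus pixels."""
    return perfusion_density(fd, annulus, exclude=artifact)


def fd_components(
    fd: BinaryMap, annulus: BinaryMap, geometry: ScanGeometry
) -> tuple[int, float]:
    """Count and mean size (um^2) of 8-connected FD components in the annulus.

    An empty deficit map yields ``(0, nan)``.
    """
    if fd.mask.shape != annulus.mask.shape:
        raise ValidationError("fd and annulus masks differ in shape")
    region = fd.mask & annulus.mask
    labels, count = ndimage.label(region, structure=_STRUCT8)
    if count == 0:
        return 0, float("nan")
    mean_px = region.sum() / count
    return int(count), float(mean_px * geometry.pixel_size_um**2)


def compute_all_metrics(
    scp: EnFaceImage,
    dcp: EnFaceImage,
    cc: EnFaceImage,
    faz_sup: FAZAnnotation,
    faz_deep: FAZAnnotation,
    config: PipelineConfig | None = None,
    lv_mask: BinaryMap | None = None,
) -> OCTAMetrics:
    """Run the full quantification chain on one eye's three slabs.

    Order: LV enhancement and segmentation on the SCP, mean-threshold vessel
    binarization of SCP and DCP, FAZ masking of the retinal maps, LV-artifact
    exclusion on the CC, flow-deficit binarization, then annulus
    quantification of all 13 metrics. ``lv_mask`` can override the LV
    segmentation (e.g. with a known ground-truth mask). Deterministic:
    identical inputs and config give bit-identical outputs.
    """
    config = config or PipelineConfig()
    if not (scp.geometry == dcp.geometry == cc.geometry):
        raise ValidationError("the three slabs must share one scan geometry")
    stage = "large-vessel enhancement"
    try:
        if lv_mask is None:
            resp = vp.enhance_large_vessels(scp, config.vesselness)
            lv_mask = vp.segment_large_vessels(
                resp, config.lv_quantile, config.lv_min_size_px, config.lv_close_radius_px
            )
        stage = "vessel binarization"
        scp_vessels = vp.binarize_vessels(scp)
        dcp_vessels = vp.binarize_vessels(dcp)
        stage = "FAZ masking"
        scp_vessels = vp.mask_faz(scp_vessels, faz_sup, scp.geometry)
        dcp_vessels = vp.mask_faz(dcp_vessels, faz_deep, dcp.geometry)
        stage = "CC artifact removal"
        cc, artifact = vp.remove_cc_artifacts(cc, lv_mask, config.cc_artifact_dilation_px)
        stage = "flow-deficit binarization"
        fd = vp.binarize_flow_deficits(cc, artifact)
        stage = "annulus quantification"
        annulus = make_annulus_mask(config.annulus, scp.geometry)
        lv_excl = lv_mask.mask
        if config.lv_exclusion_dilation_px > 0 and lv_excl.any():
            lv_excl = morphology.dilation(
                lv_excl, morphology.disk(config.lv_exclusion_dilation_px)
            )
        capillaries = BinaryMap(scp_vessels.mask & ~lv_excl, "vessels", "SCP")
        count, mean_size = fd_components(fd, annulus, cc.geometry)
        return OCTAMetrics(
            pd_lv_pct=perfusion_density(lv_mask, annulus),
            pd_scp_pct=perfusion_density(scp_vessels, annulus),
            pd_scp_wo_lv_pct=perfusion_density(capillaries, annulus),
            pd_dcp_pct=perfusion_density(dcp_vessels, annulus),
            faz_superficial=compute_faz_metrics(faz_sup),
            faz_deep=compute_faz_metrics(faz_deep),
            fd_density_pct=fd_density(fd, annulus, artifact),
            fd_mean_size_um2=mean_size,
            fd_count=count,
        )
    except Exception as exc:
        if isinstance(exc, (ValidationError, ConfigError, DegenerateInputError)):
            raise type(exc)(f"[{stage}] {exc}") from exc
        raise
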