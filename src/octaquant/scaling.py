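"""Ocular magnification correction and pixel/physical coordinate conversion.

OCTA instruments map scan angles to retinal distances assuming a schematic
design eye; an eye longer or shorter than that design images a larger or
smaller retinal patch than the nominal field of view. The abbreviated
axial-length form of Bennett's correction rescales the nominal scan length:

    s_actual = p * q * s        with    q = 0.01306 * (AL - 1.82)

where ``s`` is the nominal scan length in mm, ``AL`` the axial length in mm,
``q`` the ocular magnification factor and ``p`` the camera factor of the
imaging system. The default camera factor (3.382) is chosen so the design
eye of this instrument class (AL = 24.46 mm) yields unit magnification.

Magnification is applied as coordinate metadata — the corrected pixel size —
never by resampling pixel data, so binarized maps carry no interpolation
artifacts. Pixel indices are 0-based; each pixel covers a square of side
``pixel_size`` centered on its grid point, and the physical origin is the
image center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: Camera factor giving unit magnification at the 24.46 mm design eye.
DEFAULT_CAMERA_FACTOR = 3.382

#: Axial length (mm) at which Bennett's linear form crosses zero.
_BENNETT_INTERCEPT_MM = 1.82

#: Slope of Bennett's abbreviated ocular magnification factor (1/mm).
_BENNETT_SLOPE = 0.01306


def magnification_factor(axial_length_mm: float) -> float:
    """Ocular magnification factor q = 0.01306 * (AL - 1.82).

    Strictly increasing in axial length; raises :class:`DomainError` for
    axial lengths at or below 1.82 mm, where the factor would be
    non-positive (no physical eye is that short).
    """
    if axial_length_mm <= _BENNETT_INTERCEPT_MM:
        raise DomainError(
            f"axial length {axial_length_mm} mm <= {_BENNETT_INTERCEPT_MM} mm: "
            "ocular magnification factor would be non-positive"
        )
    return _BENNETT_SLOPE * (axial_length_mm - _BENNETT_INTERCEPT_MM)


def actual_scan_length(
    axial_length_mm: float,
    nominal_s_mm: float,
    camera_p: float = DEFAULT_CAMERA_FACTOR,
) -> float:
    """True retinal extent of a scan of nominal length ``nominal_s_mm``.

    ``s_actual = p * q * s``, linear in both the nominal length and the
    axial-length excess over 1.82 mm.
    """
    if nominal_s_mm < 0:
        raise DomainError(f"nominal scan length must be >= 0, got {nominal_s_mm}")
    if camera_p <= 0:
        raise DomainError(f"camera factor must be > 0, got {camera_p}")
    return camera_p * magnification_factor(axial_length_mm) * nominal_s_mm


def pixel_size(actual_scan_length_mm: float, n_pixels: int) -> float:
    """Pixel side length in micrometres for an isotropically sampled field."""
    if n_pixels <= 0:
        raise DomainError(f"n_pixels must be > 0, got {n_pixels}")
    return 1000.0 * actual_scan_length_mm / n_pixels


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of one en-face field after magnification correction.

    Parameters
    ----------
    nominal_scan_length_mm
        Side of the nominal square field (the protocol setting), mm.
    n_pixels_per_side
        Isotropic sampling, e.g. 245 for a 3 x 3 mm macular scan.
    axial_length_mm
        Measured axial length of the imaged eye, mm. Must exceed 1.82 mm.
    camera_factor
        Instrument camera factor ``p`` in Bennett's formula.
    """

    nominal_scan_length_mm: float = 3.0
    n_pixels_per_side: int = 245
    axial_length_mm: float = 24.46
    camera_factor: float = DEFAULT_CAMERA_FACTOR

    def __post_init__(self) -> None:
        if self.n_pixels_per_side <= 0:
            raise DomainError("n_pixels_per_side must be positive")
        if self.nominal_scan_length_mm <= 0:
            raise DomainError("nominal_scan_length_mm must be positive")
        # validates axial length > 1.82 mm as a side effect
        magnification_factor(self.axial_length_mm)

    @property
    def actual_scan_length_mm(self) -> float:
        return actual_scan_length(
            self.axial_length_mm, self.nominal_scan_length_mm, self.camera_factor
        )

    @property
    def pixel_size_um(self) -> float:
        return pixel_size(self.actual_scan_length_mm, self.n_pixels_per_side)

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    # -- coordinate conversion (origin at field center, x right, y down) --

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x_mm, y_mm) grids of pixel-center coordinates, field-centered."""
        n = self.n_pixels_per_side
        half = (n - 1) / 2.0
        idx = np.arange(n, dtype=float)
        x = (idx - half) * self.pixel_size_mm
        return np.meshgrid(x, x)  # x varies with column, y with row

    def mm_to_pixel(self, x_mm: float, y_mm: float) -> tuple[float, float]:
        """Physical field coordinates (mm) to fractional (col, row) indices."""
        half = (self.n_pixels_per_side - 1) / 2.0
        return x_mm / self.pixel_size_mm + half, y_mm / self.pixel_size_mm + half

    def pixel_to_mm(self, col: float, row: float) -> tuple[float, float]:
        """Fractional (col, row) indices to physical field coordinates (mm)."""
        half = (self.n_pixels_per_side - 1) / 2.0
        return (col - half) * self.pixel_size_mm, (row - half) * self.pixel_size_mm

    def to_record(self) -> dict:
        """Flat dict for the per-eye metadata CSV/JSON record."""
        return {
            "nominal_scan_length_mm": self.nominal_scan_length_mm,
            "n_pixels_per_side": self.n_pixels_per_side,
            "axial_length_mm": self.axial_length_mm,
            "camera_factor": self.camera_factor,
            "actual_scan_length_mm": self.actual_scan_length_mm,
            "pixel_size_um": self.pixel_size_um,
        }

    @classmethod
    def from_record(cls, record: dict) -> "ScanGeometry":
        return cls(
            nominal_scan_length_mm=float(record.get("nominal_scan_length_mm", 3.0)),
            n_pixels_per_side=int(record.get("n_pixels_per_side", 245)),
            axial_length_mm=float(record["axial_length_mm"]),
            camera_factor=float(record.get("camera_factor", DEFAULT_CAMERA_FACTOR)),
        )
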