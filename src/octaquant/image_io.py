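"""I/O for en-face slabs, masks, FAZ annotations, metrics tables and config.

En-face slabs are 8-bit grayscale TIFF or PNG at isotropic sampling
(typically 245 x 245 px for a nominal 3 x 3 mm field). FAZ annotations are
stored in physical millimetre coordinates (origin at the field center,
x right, y down) so that ocular magnification correction applies uniformly,
independent of the pixel grid. Masks round-trip as 8-bit PNG with 0/255
semantics.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import tifffile
from PIL import Image
from shapely.geometry import Polygon

from .errors import FormatError, MetadataError, ValidationError
from .scaling import ScanGeometry

Slab = Literal["SCP", "DCP", "CC"]
MaskLabel = Literal["vessels", "large_vessels", "flow_deficits", "faz", "artifact", "annulus"]
FAZLayer = Literal["superficial", "deep"]


@dataclass
class EnFaceImage:
    """One en-face slab of one eye with its scan geometry.

    ``pixels`` is a square 2-D uint8 array of side
    ``geometry.n_pixels_per_side``; ``signal_strength`` is the
    instrument-reported 0-10 quality index.
    """

    pixels: np.ndarray
    slab: Slab
    geometry: ScanGeometry
    signal_strength: int = 10
    eye_id: str = ""
    laterality: Literal["OD", "OS"] = "OD"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"en-face image must be 2-D, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise FormatError(f"en-face image must be square, got {self.pixels.shape}")
        n = self.geometry.n_pixels_per_side
        if self.pixels.shape != (n, n):
            raise ValidationError(
                f"image shape {self.pixels.shape} does not match geometry "
                f"({n} px per side)"
            )
        if not 0 <= self.signal_strength <= 10:
            raise ValidationError(f"signal_strength must be in 0-10, got {self.signal_strength}")


@dataclass
class BinaryMap:
    """Boolean grid with a provenance label (vessels, flow deficits, ...)."""

    mask: np.ndarray
    label: MaskLabel
    source_slab: Slab | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class FAZAnnotation:
    """Closed simple polygon delineating the FAZ of one retinal layer.

    Vertices are (x_mm, y_mm) pairs in field-centered physical coordinates.
    A duplicated closing vertex is accepted and dropped; closure is implicit.
    """

    vertices: np.ndarray
    layer: FAZLayer

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise FormatError(f"vertices must be an (n, 2) array, got shape {v.shape}")
        if v.shape[0] >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise FormatError(f"a polygon needs >= 3 vertices, got {v.shape[0]}")
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValidationError("FAZ polygon is self-intersecting or otherwise invalid")
        self.vertices = v
        if self.layer not in ("superficial", "deep"):
            raise ValidationError(f"unknown FAZ layer {self.layer!r}")

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


# ---------------------------------------------------------------------------
# images and masks


def _read_grayscale(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise FormatError(
            f"{path.name}: expected single-channel grayscale image, got shape {arr.shape}"
        )
    return arr


def read_enface(path: str | Path, metadata_record: Mapping) -> EnFaceImage:
    """Read one slab image, attaching geometry from a per-eye metadata record.

    The record must carry ``axial_length_mm`` (and optionally
    ``nominal_scan_length_mm``, ``camera_factor``, ``signal_strength``,
    ``eye_id``, ``laterality``, ``slab``). Intensities are preserved
    bit-exactly.
    """
    arr = _read_grayscale(path)
    if arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{Path(path).name}: image must be square, got {arr.shape}")
    if "axial_length_mm" not in metadata_record:
        raise MetadataError("metadata record is missing axial_length_mm")
    geometry = ScanGeometry(
        nominal_scan_length_mm=float(metadata_record.get("nominal_scan_length_mm", 3.0)),
        n_pixels_per_side=arr.shape[0],
        axial_length_mm=float(metadata_record["axial_length_mm"]),
        camera_factor=float(metadata_record.get("camera_factor", ScanGeometry.camera_factor)),
    )
    return EnFaceImage(
        pixels=arr,
        slab=metadata_record.get("slab", "SCP"),
        geometry=geometry,
        signal_strength=int(metadata_record.get("signal_strength", 10)),
        eye_id=str(metadata_record.get("eye_id", "")),
        laterality=metadata_record.get("laterality", "OD"),
    )


def write_enface(img: EnFaceImage, path: str | Path) -> None:
    path = Path(path)
    data = np.asarray(img.pixels, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        Image.fromarray(data).save(path)


def write_mask(bmap: BinaryMap, path: str | Path) -> None:
    """Store a boolean map as 8-bit PNG with 0/255 semantics."""
    Image.fromarray(np.where(bmap.mask, 255, 0).astype(np.uint8)).save(path)


def read_mask(path: str | Path, label: MaskLabel, source_slab: Slab | None = None) -> BinaryMap:
    arr = _read_grayscale(path)
    return BinaryMap(mask=arr > 127, label=label, source_slab=source_slab)


# ---------------------------------------------------------------------------
# FAZ annotations


def read_faz_annotation(path: str | Path, layer: FAZLayer | None = None) -> FAZAnnotation:
    """Read a FAZ polygon from JSON ({"layer": ..., "vertices": [[x, y], ...]})
    or from CSV with columns x_mm,y_mm (layer then passed explicitly)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        if "vertices" not in payload:
            raise FormatError(f"{path.name}: annotation JSON lacks a 'vertices' field")
        vertices = payload["vertices"]
        layer = layer or payload.get("layer")
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"x_mm", "y_mm"} <= set(reader.fieldnames):
                raise FormatError(f"{path.name}: annotation CSV needs columns x_mm,y_mm")
            vertices = [[float(r["x_mm"]), float(r["y_mm"])] for r in reader]
    if layer is None:
        raise MetadataError("FAZ layer not given in file nor as argument")
    return FAZAnnotation(vertices=np.asarray(vertices, dtype=float), layer=layer)


def write_faz_annotation(faz: FAZAnnotation, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"layer": faz.layer, "vertices": faz.vertices.tolist()}, fh, indent=1)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x_mm", "y_mm"])
            writer.writerows(faz.vertices.tolist())


# ---------------------------------------------------------------------------
# metrics tables and config

#: Canonical column order for the 13 per-eye metrics.
METRIC_COLUMNS = [
    "pd_lv_pct",
    "pd_scp_pct",
    "pd_scp_wo_lv_pct",
    "pd_dcp_pct",
    "faz_sup_area_mm2",
    "faz_sup_perimeter_mm",
    "faz_sup_circularity",
    "faz_deep_area_mm2",
    "faz_deep_perimeter_mm",
    "faz_deep_circularity",
    "fd_density_pct",
    "fd_size_um2",
    "fd_number",
]


def write_metrics_table(records: Sequence[Mapping], path: str | Path) -> None:
    """Write per-eye metric rows to CSV: eye_id first, then the 13 metrics.

    Rows must share one schema; duplicate eye_ids are rejected.
    """
    import pandas as pd

    columns = ["eye_id"] + METRIC_COLUMNS
    rows = []
    seen: set = set()
    for rec in records:
        missing = [c for c in columns if c not in rec]
        if missing:
            raise ValidationError(f"record lacks columns {missing}")
        if rec["eye_id"] in seen:
            raise ValidationError(f"duplicate eye_id {rec['eye_id']!r}")
        seen.add(rec["eye_id"])
        rows.append({c: rec[c] for c in columns})
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False, float_format="%.6f")


def read_metrics_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path)


def read_config(path: str | Path) -> dict:
    """Flat key-value JSON config (camera factor, annulus diameters,
    filter parameters, thresholds, seed)."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config must be a JSON object")
    return cfg
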