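"""Synthetic en-face slabs and cohorts with known ground truth.

No public OCTA scan repository accompanies healthy-cohort comparison
studies, so every pipeline stage is exercised on generated data instead:

* retinal slabs (SCP/DCP) are random curvilinear capillary meshes —
  random-walk strokes dilated to capillary calibre — with a radially
  perturbed star-polygon FAZ carved out and, for the SCP, thick smooth
  large-vessel tracks;
* choriocapillaris slabs are a bright flow background with dark deficit
  blobs planted on a separated grid (minimum 2 px gaps, so 8-connected
  component counting is unambiguous);
* cohorts are drawn per group from independent normal (continuous) and
  Bernoulli (categorical) distributions with the published healthy-cohort
  group means, SDs and proportions as defaults.

Images use a two-level ("bimodal") intensity construction: with zero noise
the mean-intensity and mean-minus-SD thresholding rules provably recover
the planted masks pixel-for-pixel, which makes the generator the oracle for
the binarization stages. Planted pixel counts inside the measurement
annulus are adjusted to the exact rounded target, so recovered densities
equal the planted fractions without tolerance. All generators are pure
functions of (recipe, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from skimage import draw, morphology

from .errors import GenerationError, ValidationError
from .image_io import EnFaceImage, FAZAnnotation
from .region_metrics import AnnulusSpec, make_annulus_mask
from .scaling import ScanGeometry
from .vessel_processing import rasterize_polygon


# ---------------------------------------------------------------------------
# recipes

@dataclass(frozen=True)
class SlabRecipe:
    """Targets and levels for one synthetic slab.

    Fraction targets refer to the measurement annulus (and, for vessels,
    also the rest of the field outside the FAZ). ``foreground_level`` is
    the flowing-signal intensity, ``background_level`` the avascular /
    flow-deficit intensity.
    """

    slab: Literal["SCP", "DCP", "CC"]
    vessel_fraction_target: float = 0.42
    lv_fraction_target: float = 0.0
    faz_area_mm2_target: float = 0.34
    faz_irregularity: float = 0.3
    fd_fraction_target: float = 0.17
    fd_blob_count: int = 1379
    foreground_level: int = 200
    background_level: int = 40
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.vessel_fraction_target < 1:
            raise ValidationError("vessel_fraction_target must be in (0, 1)")
        if not 0 <= self.lv_fraction_target < self.vessel_fraction_target:
            raise ValidationError("lv_fraction_target must be in [0, vessel fraction)")
        if not 0 < self.fd_fraction_target < 0.5:
            raise ValidationError(
                "fd_fraction_target must be in (0, 0.5) for the mean-SD rule to separate levels"
            )
        if self.foreground_level <= self.background_level:
            raise ValidationError("foreground_level must exceed background_level")


def default_recipe(slab: str, seed: int = 0) -> SlabRecipe:
    """Recipe whose targets sit at the published healthy-macula group means
    (SCP PD 42.4%, LV PD 6.7%, DCP PD 39.1%, FD density 17.2%, FD number
    1379, superficial FAZ 0.34 mm^2, deep FAZ 1.14 mm^2)."""
    presets = {
        "SCP": dict(vessel_fraction_target=0.424, lv_fraction_target=0.067,
                    faz_area_mm2_target=0.34, faz_irregularity=0.35),
        "DCP": dict(vessel_fraction_target=0.391, lv_fraction_target=0.0,
                    faz_area_mm2_target=1.14, faz_irregularity=0.2),
        "CC": dict(fd_fraction_target=0.172, fd_blob_count=1379),
    }
    if slab not in presets:
        raise ValidationError(f"unknown slab {slab!r}")
    return SlabRecipe(slab=slab, seed=seed, **presets[slab])


# ---------------------------------------------------------------------------
# FAZ polygon

def generate_faz_polygon(
    area_mm2_target: float,
    irregularity: float,
    n_vertices: int = 64,
    seed: int = 0,
    layer: Literal["superficial", "deep"] = "superficial",
) -> FAZAnnotation:
    """Radially perturbed star polygon rescaled to the exact target area.

    The radius is modulated by random low-order harmonics (modes 2-5) of
    total relative amplitude ``irregularity``, giving smooth lobed outlines
    like manually traced avascular zones rather than high-frequency zigzag.
    ``irregularity`` 0 gives a regular n-gon (circularity -> 1 as n grows).
    The rescale is exact because polygon area scales with the square of the
    coordinates.
    """
    if area_mm2_target <= 0:
        raise ValidationError("area target must be positive")
    if n_vertices < 8:
        raise ValidationError("need at least 8 vertices")
    rng = np.random.default_rng(seed)
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = np.ones(n_vertices)
    if irregularity > 0:
        modes = np.arange(2, 6)
        amps = rng.uniform(0.3, 1.0, modes.size)
        amps *= irregularity / amps.sum()
        phases = rng.uniform(0.0, 2.0 * np.pi, modes.size)
        for m, a, ph in zip(modes, amps, phases):
            radii += a * np.cos(m * angles + ph)
    radii = np.clip(radii, 0.05, None)
    verts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    faz = FAZAnnotation(vertices=verts, layer=layer)
    from .faz_metrics import polygon_area  # local import avoids a cycle at import time

    scale = np.sqrt(area_mm2_target / polygon_area(faz))
    return FAZAnnotation(vertices=verts * scale, layer=layer)


# ---------------------------------------------------------------------------
# slab images

def _adjust_region_count(
    mask: np.ndarray, region: np.ndarray, target_count: int,
    rng: np.random.Generator, protected: np.ndarray | None = None,
) -> None:
    """Flip random pixels inside ``region`` until ``mask & region`` has
    exactly ``target_count`` True pixels. ``protected`` pixels are never
    switched off. In-place."""
    current = int((mask & region).sum())
    if current < target_count:
        candidates = np.flatnonzero(region & ~mask)
        need = target_count - current
        if need > candidates.size:
            raise GenerationError("target fraction exceeds available region")
        pick = rng.choice(candidates, size=need, replace=False)
        mask.ravel()[pick] = True
    elif current > target_count:
        removable = mask & region
        if protected is not None:
            removable = removable & ~protected
        candidates = np.flatnonzero(removable)
        drop = current - target_count
        if drop > candidates.size:
            raise GenerationError("cannot reach target without removing protected pixels")
        pick = rng.choice(candidates, size=drop, replace=False)
        mask.ravel()[pick] = False


def _stroke_mesh(
    n: int, target_fraction: float, allowed: np.ndarray, rng: np.random.Generator,
    step_px: float = 3.0, n_steps: int = 40, wiggle: float = 0.25,
    calibre_radius: int = 1, max_strokes: int = 6000,
) -> np.ndarray:
    """Random-walk capillary mesh dilated to calibre, grown until the
    fraction of ``allowed`` pixels covered approaches the target."""
    centerlines = np.zeros((n, n), dtype=bool)
    footprint = morphology.disk(calibre_radius)
    mesh = np.zeros_like(centerlines)
    n_allowed = int(allowed.sum())
    strokes = 0
    while strokes < max_strokes:
        for _ in range(20):
            r, c = rng.uniform(0, n - 1, 2)
            heading = rng.uniform(0, 2 * np.pi)
            for _ in range(n_steps):
                heading += rng.normal(0.0, wiggle)
                r2 = r + step_px * np.sin(heading)
                c2 = c + step_px * np.cos(heading)
                rr, cc = draw.line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
                keep = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
                centerlines[rr[keep], cc[keep]] = True
                r, c = r2, c2
                if not (0 <= r < n and 0 <= c < n):
                    break
            strokes += 1
        mesh = morphology.dilation(centerlines, footprint)
        if (mesh & allowed).sum() / n_allowed >= target_fraction:
            return mesh
    return mesh  # close enough; exact adjustment tops it up


def _lv_tracks(
    n: int, rng: np.random.Generator, n_tracks: int = 4, half_width: int = 3
) -> np.ndarray:
    """Thick, smooth vessel tracks crossing the field (arteriole calibre)."""
    centerlines = np.zeros((n, n), dtype=bool)
    for _ in range(n_tracks):
        edge = rng.integers(4)
        t = rng.uniform(0.15, 0.85) * (n - 1)
        r, c = [(0.0, t), (n - 1.0, t), (t, 0.0), (t, n - 1.0)][edge]
        heading = [np.pi / 2, -np.pi / 2, 0.0, np.pi][edge] + rng.normal(0, 0.25)
        for _ in range(int(n / 2)):
            heading += rng.normal(0.0, 0.08)
            r2, c2 = r + 3.0 * np.sin(heading), c + 3.0 * np.cos(heading)
            rr, cc = draw.line(int(round(r)), int(round(c)), int(round(r2)), int(round(c2)))
            keep = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            centerlines[rr[keep], cc[keep]] = True
            r, c = r2, c2
            if not (0 <= r < n and 0 <= c < n):
                break
    return morphology.dilation(centerlines, morphology.disk(half_width))


def _peel_to_count(
    mask: np.ndarray, region: np.ndarray, target_count: int, rng: np.random.Generator
) -> None:
    """Erode a thick mask from its boundary until ``mask & region`` hits the
    target count exactly, preserving connected shapes. In-place."""
    while int((mask & region).sum()) > target_count:
        boundary = mask & ~morphology.erosion(mask, morphology.disk(1))
        candidates = np.flatnonzero(boundary & region)
        excess = int((mask & region).sum()) - target_count
        if candidates.size == 0:
            candidates = np.flatnonzero(mask & region)
        pick = rng.choice(candidates, size=min(excess, candidates.size), replace=False)
        mask.ravel()[pick] = False


def _blob_offsets(size: int, side: int) -> list[tuple[int, int]]:
    """Row-major fill of a ``side x side`` footprint; every prefix is one
    8-connected component."""
    return [(r, c) for r in range(side) for c in range(side)][:size]


def _plant_fd_blobs(
    annulus: np.ndarray, total_px: int, n_blobs: int, rng: np.random.Generator
) -> np.ndarray:
    """Plant ``n_blobs`` dark blobs totalling ``total_px`` pixels inside the
    annulus, on a grid that guarantees >= 2 px separation."""
    if n_blobs <= 0 or total_px < n_blobs:
        raise GenerationError("need at least one pixel per blob")
    base = total_px // n_blobs
    n_big = total_px - base * n_blobs  # blobs of size base + 1
    max_size = base + (1 if n_big else 0)
    side = int(np.ceil(np.sqrt(max_size)))
    spacing = side + 2  # >= 2 px gap between footprints
    n = annulus.shape[0]
    sites = [
        (r, c)
        for r in range(0, n - side + 1, spacing)
        for c in range(0, n - side + 1, spacing)
        if annulus[r : r + side, c : c + side].all()
    ]
    if len(sites) < n_blobs:
        raise GenerationError(
            f"annulus holds {len(sites)} separated sites < {n_blobs} blobs requested"
        )
    chosen = rng.choice(len(sites), size=n_blobs, replace=False)
    sizes = np.full(n_blobs, base)
    sizes[:n_big] += 1
    rng.shuffle(sizes)
    fd = np.zeros_like(annulus)
    for idx, size in zip(chosen, sizes):
        r0, c0 = sites[idx]
        for dr, dc in _blob_offsets(int(size), side):
            fd[r0 + dr, c0 + dc] = True
    return fd


def generate_enface(
    recipe: SlabRecipe,
    geometry: ScanGeometry | None = None,
    annulus_spec: AnnulusSpec | None = None,
) -> tuple[EnFaceImage, dict]:
    """Generate one synthetic slab plus its ground truth.

    Returns the image and a truth dict with the pre-noise masks
    (``vessel_mask``, ``lv_mask``, ``fd_mask``, all boolean arrays or None),
    the ``faz_polygon`` annotation, the ``annulus`` mask used for count
    adjustment, and the realized annulus fractions
    (``vessel_fraction_annulus`` etc.), which the planted pixel counts hit
    exactly at the rounded target.
    """
    geometry = geometry or ScanGeometry()
    annulus_spec = annulus_spec or AnnulusSpec()
    n = geometry.n_pixels_per_side
    rng = np.random.default_rng(recipe.seed)
    annulus = make_annulus_mask(annulus_spec, geometry).mask
    n_annulus = int(annulus.sum())
    truth: dict = {"annulus": annulus, "vessel_mask": None, "lv_mask": None,
                   "fd_mask": None, "faz_polygon": None}

    if recipe.slab in ("SCP", "DCP"):
        layer = "superficial" if recipe.slab == "SCP" else "deep"
        faz = generate_faz_polygon(
            recipe.faz_area_mm2_target, recipe.faz_irregularity,
            seed=int(rng.integers(2**31)), layer=layer,
        )
        faz_px = rasterize_polygon(faz, geometry)
        outside_faz = ~faz_px

        lv = np.zeros((n, n), dtype=bool)
        if recipe.slab == "SCP" and recipe.lv_fraction_target > 0:
            lv_target = int(round(recipe.lv_fraction_target * n_annulus))
            for _ in range(40):  # bounded retries: add tracks until covered
                lv |= _lv_tracks(n, rng)
                lv &= outside_faz
                if int((lv & annulus).sum()) >= lv_target:
                    break
            else:
                raise GenerationError("could not reach the large-vessel fraction target")
            _peel_to_count(lv, annulus, lv_target, rng)

        mesh = _stroke_mesh(n, recipe.vessel_fraction_target, outside_faz, rng)
        vessels = (mesh | lv) & outside_faz

        # exact planted counts: the annulus hits round(f * |annulus|) so the
        # recovered perfusion density equals the planted fraction; the rest
        # of the field is adjusted to its own region fraction
        in_ann = annulus & outside_faz
        out_ann = ~annulus & outside_faz
        _adjust_region_count(
            vessels, in_ann, int(round(recipe.vessel_fraction_target * n_annulus)),
            rng, protected=lv,
        )
        _adjust_region_count(
            vessels, out_ann,
            int(round(recipe.vessel_fraction_target * int(out_ann.sum()))),
            rng, protected=lv,
        )
        truth.update(
            vessel_mask=vessels, lv_mask=lv, faz_polygon=faz,
            vessel_fraction_annulus=(vessels & annulus).sum() / n_annulus,
            lv_fraction_annulus=(lv & annulus).sum() / n_annulus,
            # same expression as perfusion_density, so equality is bitwise
            vessel_pd_pct=100.0 * int((vessels & annulus).sum()) / n_annulus,
            lv_pd_pct=100.0 * int((lv & annulus).sum()) / n_annulus,
        )
        image = np.where(vessels, recipe.foreground_level, recipe.background_level)
    else:  # CC
        total = int(round(recipe.fd_fraction_target * n_annulus))
        fd = _plant_fd_blobs(annulus, total, recipe.fd_blob_count, rng)
        truth.update(
            fd_mask=fd,
            fd_fraction_annulus=(fd & annulus).sum() / n_annulus,
            fd_density_pct=100.0 * int((fd & annulus).sum()) / n_annulus,
            fd_blob_count=recipe.fd_blob_count,
        )
        image = np.where(fd, recipe.background_level, recipe.foreground_level)

    image = image.astype(float)
    if recipe.noise_sd > 0:
        image = image + rng.normal(0.0, recipe.noise_sd, image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    enface = EnFaceImage(pixels=image, slab=recipe.slab, geometry=geometry)
    return enface, truth


def generate_eye(
    seed: int = 0,
    geometry: ScanGeometry | None = None,
    noise_sd: float = 0.0,
) -> tuple[dict, dict]:
    """Generate a full synthetic eye: SCP, DCP and CC slabs with shared
    geometry and default targets. Returns (slabs, truths) keyed by slab."""
    geometry = geometry or ScanGeometry()
    slabs, truths = {}, {}
    for i, slab in enumerate(("SCP", "DCP", "CC")):
        recipe = replace(default_recipe(slab, seed=seed * 3 + i), noise_sd=noise_sd)
        slabs[slab], truths[slab] = generate_enface(recipe, geometry)
    return slabs, truths


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortRecipe:
    """Group sizes and per-variable distributions for a two-group cohort.

    ``continuous`` maps a column to ((mean1, sd1), (mean2, sd2));
    ``binary`` maps a column to (p1, p2). Variables are drawn independently
    (no cross-variable correlation)."""

    group_names: tuple[str, str] = ("Chinese", "Caucasian")
    n_per_group: tuple[int, int] = (92, 99)
    continuous: dict = field(default_factory=dict)
    binary: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for var, pair in self.continuous.items():
            for _, sd in pair:
                if sd < 0:
                    raise ValidationError(f"{var}: sd must be >= 0")
        for var, (p1, p2) in self.binary.items():
            if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
                raise ValidationError(f"{var}: proportions must be in [0, 1]")


#: Published two-group healthy-cohort parameters: characteristics and the
#: 13 OCTA metrics, (Chinese, Caucasian) order.
TABLE_PRESET_CONTINUOUS = {
    "age": ((44.0, 13.0), (42.0, 14.0)),
    "axial_length_mm": ((24.7, 1.5), (23.2, 0.9)),
    "spherical_equivalent": ((-2.4, 3.3), (-0.1, 1.9)),
    "iop_mmHg": ((16.8, 3.3), (15.1, 2.4)),
    "signal_strength": ((9.3, 0.9), (9.4, 1.0)),
    "pd_lv_pct": ((6.7, 0.8), (6.6, 0.8)),
    "pd_scp_pct": ((42.4, 2.6), (40.9, 2.5)),
    "pd_scp_wo_lv_pct": ((29.6, 2.6), (28.6, 2.4)),
    "pd_dcp_pct": ((39.1, 3.6), (40.1, 3.4)),
    "faz_sup_area_mm2": ((0.34, 0.1), (0.28, 0.1)),
    "faz_sup_perimeter_mm": ((2.41, 0.6), (2.14, 0.5)),
    "faz_sup_circularity": ((1.19, 0.2), (1.18, 0.1)),
    "faz_deep_area_mm2": ((1.14, 0.3), (1.11, 0.3)),
    "faz_deep_perimeter_mm": ((4.04, 0.6), (4.12, 0.6)),
    "faz_deep_circularity": ((1.08, 0.1), (1.11, 0.1)),
    "fd_density_pct": ((17.2, 1.7), (16.7, 1.6)),
    "fd_size_um2": ((508.0, 96.0), (496.0, 91.0)),
    "fd_number": ((1379.0, 129.0), (1407.0, 121.0)),
}

TABLE_PRESET_BINARY = {
    "sex_female": (63 / 92, 63 / 99),
    "diabetes": (0.0, 2 / 99),
    "hypertension": (17 / 92, 11 / 99),
}


def table_preset(seed: int = 0, n_per_group: tuple[int, int] = (92, 99)) -> CohortRecipe:
    """Cohort recipe with the published group means/SDs/proportions."""
    return CohortRecipe(
        n_per_group=n_per_group,
        continuous=dict(TABLE_PRESET_CONTINUOUS),
        binary=dict(TABLE_PRESET_BINARY),
        seed=seed,
    )


def null_preset(seed: int = 0, n_per_group: tuple[int, int] = (92, 99)) -> CohortRecipe:
    """Same marginal distributions in both groups (group-1 parameters)."""
    base = table_preset(seed, n_per_group)
    return replace(
        base,
        continuous={k: (v[0], v[0]) for k, v in base.continuous.items()},
        binary={k: (v[0], v[0]) for k, v in base.binary.items()},
    )


def generate_cohort(recipe: CohortRecipe) -> pd.DataFrame:
    """Draw a synthetic two-group participant table, reproducible by seed.

    Age is truncated below at 18 and signal strength clipped to [0, 10];
    ``sex_female`` becomes the categorical ``sex`` column ('F'/'M') and the
    other binaries become booleans.
    """
    rng = np.random.default_rng(recipe.seed)
    frames = []
    for gi, (name, n) in enumerate(zip(recipe.group_names, recipe.n_per_group)):
        data: dict = {
            "participant_id": [f"{name[:3].upper()}{i:04d}" for i in range(n)],
            "ethnicity": name,
        }
        for var, pair in recipe.continuous.items():
            mean, sd = pair[gi]
            data[var] = rng.normal(mean, sd, n)
        for var, ps in recipe.binary.items():
            data[var] = rng.random(n) < ps[gi]
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True)
    if "age" in table:
        table["age"] = table["age"].clip(lower=18.0)
    if "signal_strength" in table:
        table["signal_strength"] = table["signal_strength"].clip(0.0, 10.0)
    if "sex_female" in table:
        table["sex"] = np.where(table.pop("sex_female"), "F", "M")
    return table
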