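# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `octaquant`. It covers the measurement pipeline for
en-face OCTA slabs, the cohort statistics, and the synthetic-data generator
used in place of raw scans.

## Ocular magnification

OCTA instruments convert scan angles into retinal distances assuming a
schematic design eye. The package applies the abbreviated (axial-length
only) Bennett correction, `s_actual = p · q · s` with
`q = 0.01306 · (AL − 1.82)`. The linear form crosses zero at
AL = 1.82 mm, so axial lengths at or below that are rejected as physically
impossible.

The camera factor `p` is instrument-specific and rarely published. The
default, **p = 3.382**, is fixed by requiring unit magnification
(`p · q = 1`) at the 24.46 mm design eye of the instrument class that
produces 3 × 3 mm, 245 × 245 px macular scans; it is a config knob
(`camera_factor`) for other devices. The full Littmann three-variable
correction (corneal curvature, refraction, axial length) is out of scope.

Correction is applied to coordinate metadata — the pixel size becomes
`1000 · s_actual / 245` µm — never by resampling the image. Resampling a
binarized map would interpolate mask edges; adjusting the pixel size leaves
pixel counts exact and scales all physical measurements consistently.
Pixel indices are 0-based; each pixel is a square of side `pixel_size`
centered on its grid point; the physical origin is the image center, x
right, y down. The fovea-centered annulus is defined in corrected
millimetres, i.e. post-correction, following the convention that the region
of measurement is magnification-corrected.

## Vessel and flow-deficit binarization

Two global thresholding rules drive all regional metrics. Their boundary
conventions are deliberate and covered by tests:

- **Vessels (SCP, DCP):** pixel is vessel iff intensity ≥ the mean of the
  *full* image (computed before FAZ masking). The inclusive rule makes a
  constant image all-vessel; the alternative (strict >) would make it empty.
  Either is defensible; one had to be fixed.
- **Flow deficits (CC):** pixel is deficit iff intensity < mean − SD, with
  mean and SD computed over non-artifact pixels only. The strict rule makes
  a constant image deficit-free (SD = 0 means no pixel is *below* the
  mean-minus-SD threshold). The SD uses divisor N (population form); at
  60,025 pixels the difference from N−1 is negligible, but fixing it makes
  results bit-reproducible.

Both rules are invariant under positive affine intensity transforms, which
is what makes a global mean threshold meaningful on instrument-normalized
8-bit exports.

Excluding artifact pixels from the CC statistics (rather than thresholding
the full image) is an interpretation: large-vessel shadows are dark, so
including them would bias the mean and SD downward and shift the deficit
threshold. The artifact mask is the SCP large-vessel mask dilated by 1 px
(configurable); artifact pixels are excluded from numerator and denominator
of all CC metrics, not inpainted.

## Large-vessel enhancement and segmentation

Arterioles and venules in the SCP are enhanced by the pixelwise maximum of
two normalized responses:

- a Gabor magnitude bank: 12 orientations (15° steps), wavelength 8 px
  (≈ 100 µm at 12.24 µm/px — large-vessel calibre), bandwidth 1 octave;
- Sato tubularity (Hessian eigenvalue measure) at σ ∈ {2, 3, 4} px, bright
  ridges.

Each response is min-max normalized to [0, 1] with a flat-image guard
(range < 1e-12 maps to zero) before combination. Segmentation thresholds
the combined response at its 0.92 quantile (strict >, so a zero response
yields an empty mask and raising the quantile never adds pixels), removes
components below 50 px and closes with a 1 px disk. The original analysis
names the filter families but no parameters; these defaults are sized to
large-vessel calibre and are all configurable. Whether the original
thresholding was global or adaptive is unknown; the global quantile is this
package's choice.

**"SCP without LVs"** subtracts the LV mask *dilated by 3 px* from the
numerator while keeping the full annulus as denominator. Reported
healthy-macula values (total SCP ≈ 42%, LVs ≈ 7%, SCP w/o LVs ≈ 30%) are
incompatible with a plain subtraction (42 − 7 = 35), implying the original
exclusion also removed peri-vascular signal; the dilation radius is
configurable and flagged as an interpretation.

## FAZ morphometry

FAZ metrics are computed on the annotated polygon in millimetre
coordinates, never on a rasterized mask (rasterization is used only for
masking vessel maps, by the pixel-center rule). Area is the absolute
shoelace area, perimeter the closed vertex-distance sum (both via shapely).
Circularity is `P / (2·√(π·A))` — the perimeter over that of the equal-area
circle — which is ≥ 1 by the isoperimetric inequality with 1 for a perfect
circle. This convention (rather than the roundness `4πA/P² ≤ 1`) matches
healthy-macula reports of circularities slightly above 1. Manual outlines
are measured as drawn; no smoothing is applied before the perimeter sum.

## Regional quantification

A pixel belongs to the annulus iff its center lies at
`inner_radius ≤ d < outer_radius` from the annulus center (default
diameters 1.0/2.5 mm; inner 0 degenerates to a disk). The pixel-center rule
keeps membership exactly countable in tests; at 245 px over 3 mm the
rasterized annulus fraction agrees with the analytic value
`π(1.25² − 0.5²)/9 ≈ 0.4581` to well under 1%.

Perfusion density is `100 · |vessels ∧ annulus| / |annulus|`; FD density
uses the non-artifact annulus in both numerator and denominator. FD
components are labelled with 8-connectivity and no minimum-size filter;
mean component size is mean pixel count × pixel area (µm²), reported as
missing (NaN) when there are no components. FAZ regions are masked from
retinal vessel maps before quantification; with the default annulus the
inner disk already excludes typical superficial FAZ extents, but deep FAZs
(≈ 1.1 mm², radius ≈ 0.6 mm) cross the 0.5 mm inner radius, so masking
matters there.

## Cohort statistics

- Spherical equivalent = sphere + cylinder/2 (diopters).
- Exclusion: signal strength < 6, or any grader flag (motion, floater,
  misalignment, segmentation); one reason logged per eye, signal strength
  checked first.
- Random eye choice seeds a generator with (seed, CRC32 of participant id):
  reproducible per participant, balanced across participants.
- Group tests: pooled-variance (Student) t by default — the common default
  of the statistical environments used for such analyses, and the form that
  reproduces recomputable published p-values from summary data; Welch via
  `equal_var=False`. Chi-square is Pearson without Yates continuity
  correction: with the correction, a 0-vs-2 diabetes split gives p ≈ 0.5,
  contradicting the published 0.171, while the uncorrected form reproduces
  0.480/0.171/0.150.
- Adjusted comparisons: OLS of each metric on the group indicator plus age,
  diabetes, hypertension, signal strength, spherical equivalent,
  intraocular pressure and axial length (binaries as 0/1; sex is not an
  adjuster because cohorts are age- and sex-matched by design). Spherical
  equivalent is included by default — the published model definition lists
  it — and can be dropped via the `adjusters` argument. Zero-variance
  adjusters are dropped with a warning (a constant column is uninformative
  and would only make the design singular); explicit calls to
  `adjusted_group_difference` instead raise a singular-design error naming
  the offending columns. No multiple-testing correction is applied; each
  metric is tested at α = 0.05.

## Synthetic data

The generator exists because raw scans from healthy-cohort OCTA studies are
not publicly deposited. Its defaults sit at the published group values:
SCP PD 42.4%, LV PD 6.7%, DCP PD 39.1%, CC FD density 17.2% with 1379
deficits, superficial/deep FAZ areas 0.34/1.14 mm²; the cohort presets
embed the full published group means, SDs and proportions
(`table_preset`) or a no-effect variant (`null_preset`).

Design choices that make the generator an *oracle*:

- **Two-level intensities.** Vessel pixels get one level (default 200),
  background another (default 40). With zero noise the mean lies strictly
  between the levels, so the mean-threshold rule provably recovers the
  planted mask pixel-for-pixel; likewise mean − SD separates the two CC
  levels whenever the deficit fraction is below 0.5 (hence the recipe
  bound).
- **Exact counts.** After growing a random-walk capillary mesh to within
  0.01 of the target fraction, pixel counts inside the annulus (and,
  separately, in the rest of the field outside the FAZ) are adjusted to the
  exact rounded target, so recovered densities equal planted values without
  tolerance. Large-vessel tracks are peeled from their boundary to the
  exact count, preserving their shape.
- **Separated FD blobs.** Deficit blobs are square-ish footprints placed on
  a grid with ≥ 2 px gaps, so 8-connected counting is unambiguous and the
  component count equals the planted blob count exactly. At the default
  1379 blobs and 17.2% density, mean blob size ≈ 3.4 px ≈ 515 µm² at the
  design-eye pixel size — consistent with published FD sizes near 508 µm².
- **Smooth FAZ outlines.** The FAZ polygon perturbs a circle with random
  low-order harmonics (modes 2–5) of total amplitude `irregularity`, then
  rescales to the exact target area (area scales quadratically, so the
  rescale is exact). Irregularity 0 gives a regular n-gon; ≈ 0.35 yields
  circularities near 1.1–1.15, matching healthy-macula reports.
- All generators are pure functions of (recipe, seed).

What the generator does **not** emulate: OCTA speckle and decorrelation
statistics, projection artifacts in the DCP, vascular tree topology and
hemodynamics, LV shadows in the CC slab, signal-strength gradients, motion
artifacts, or correlations between cohort variables (each variable is drawn
independently; age is truncated at 18, signal strength clipped to [0, 10]).
Passing tests therefore demonstrate that the measurement chain is correct
and stable under moderate additive noise — not that the thresholding rules
are optimal on real speckle.

## Problem sizes and numerics

Tests and the acceptance script run at the native 245 × 245 px slab size.
Simulation-based checks use 500 replicates for parameter recovery and
power, 1000 for type-I error, and 10–200 replicate cohorts elsewhere —
enough for the binomial error of a rate estimate to sit well inside the
asserted bands. Degenerate inputs are handled explicitly: an empty
measurement region, an all-artifact CC slab, a zero-area polygon and a
zero-margin contingency table raise typed errors rather than returning
NaNs; a deficit-free CC reports count 0 and missing mean size.

## Known limitations

- The LV segmentation is a heuristic; on synthetic meshes where capillaries
  and LVs share one intensity level it recovers only part of the planted LV
  area (calibre is the only separating feature). Ground-truth LV masks can
  be injected via `compute_all_metrics(lv_mask=...)`.
- The published per-group metric means derive from real scans and are not
  reproducible from synthetic data; the package reproduces the *statistics*
  computed from published counts and summaries, and the planted-value
  recovery on synthetic inputs.
- The 1:1 age–sex matching procedure of cohort construction is not
  implemented (the algorithm is not specified in the source analyses); the
  package starts from an already-matched participant table.
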