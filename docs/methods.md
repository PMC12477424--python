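# Methods

This note documents the models and procedures implemented in `reefscape`,
the defaults they use, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Rasters and geometry

A DEM is a single-band elevation raster with square cells
(`DEMGrid`). Coordinates are continuous meters with cell-center
registration: cell `(i, j)` has its center at
`origin + ((j + 0.5)·c, (i + 0.5)·c)` for cell size `c`. This makes
bilinear interpolation and quadrat cropping unambiguous. Nodata cells are
NaN; any operation whose stencil touches nodata raises rather than
interpolating across the gap — silent smoothing over reconstruction holes
would bias every metric downstream.

GeoTIFF I/O uses `tifffile` with the minimal georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL nodata); ESRI ASCII grids are read
and written directly. Non-square pixels are rejected. Round trips
preserve elevations to float32 precision (≤ 1e-6 m for reef-scale
values) and the nodata mask exactly.

Cross-sections are sampled at stations `0, step, 2·step, …` with the
endpoint always included, elevations bilinearly interpolated from the
four surrounding cell centers. Random cross-sections run parallel to the
transect long axis at a uniformly random longitudinal offset and
transverse position (both seeded and logged); the protocol this emulates
does not state whether sections may be oblique, so axis-parallel is the
default and is recorded in the profile metadata.

Random 1-m² quadrats avoid an edge margin. The nominal default margin of
one quadrat side cannot be honored on a 2-m-wide transect (1 m quadrat +
two 1 m margins > 2 m), so the requested margin is clamped per axis to
the widest feasible value; an error is raised only when the quadrat
itself does not fit. Placements are seeded and logged via each quadrat's
origin.

## Field of view

* `eye_height` = 0.02 m — approximate eye height of small reef fish over
  the substrate. Exposed in `FovConfig`, never auto-scaled with body size.
* `reach` = 1.8 m — the mean predator starting distance in the flight
  experiments; sight lines longer than this are behaviorally irrelevant.
* `station_step` = 0.5 m on a `section_length` = 10 m cross-section,
  stations aiming toward the section center with the central station
  measured both ways: 22 measurements, averaged to one transect value.

"The highest point the sight line can reach" is interpreted as the point
*maximizing the elevation angle* within the Euclidean reach of the eye,
not the maximum-elevation point — the angle, not the raw height, controls
occlusion, and the two coincide on monotone obstacles. Both
interpretations are implemented (`FovConfig.target`), highest-angle being
the default. Negative maximum angles (eye above all terrain in reach)
clamp to 0°, i.e. fov = 1: a 2D hemifield cannot be more than fully
open. The station's own column is excluded from candidates to avoid a
zero horizontal offset. Angles above 90° cannot arise from `atan`; the
normalization clamps to [0°, 90°] regardless.

The implementation evaluates every profile sample within reach, so it is
by construction equal to the exhaustive oracle; the test suite still
checks this equivalence against an independently coded maximizer.

## Refuge detection

A cell is flagged when `local_mean − elevation ≥ threshold`, with the
local mean taken over a square moving window of side 0.5 m (~17 cells at
3 cm/pixel), centered on the cell, truncated at edges, valid cells only.
"Significantly lower" is a hard threshold, not a statistical test.
The window side is a config knob: the source method leaves it
unspecified, and 0.5 m is commensurate with the scale of fish-sized
refuges. Flagged cells are grouped under 8-connectivity (default;
4-connectivity available), components smaller than `min_area` (default 1
cell) are discarded, and density is components per m² of valid quadrat
area. Window means use exact integral-image sums, so they agree with
direct per-cell averaging to float precision.

Flagged sets are nested across ascending thresholds. Component *counts*
are monotone for isolated pits but can locally invert on very rough
surfaces, where one broad shallow blob fragments into several deeper
cores — the tests assert monotonicity only where it is guaranteed.

DEMs are 2.5D: overhangs and roofed cavities are unrepresentable, so
this metric undercounts true refuges on morphologically complex reefs.
That is a limitation of the underlying raster representation, not of the
implementation.

## Rugosity

`rugosity = 1 − planar_area / surface_area_3D ∈ [0, 1)`. The 3D area
triangulates each quad of four adjacent cell centers into two triangles
along a fixed NW–SE diagonal; an alternating (checkerboard) diagonal is
available because the choice perturbs areas in the 3rd–4th decimal on
rough grids. Quads touching nodata are excluded from both areas so the
ratio compares like-for-like regions. The metric is exactly 0 for a
horizontal plane, invariant to constant elevation offsets, and
`1 − cos(α)` for a plane inclined at α. Areas are computed on the DEM,
not on any pre-rasterization mesh.

## Site comparisons

* Levene's test defaults to median centering (Brown–Forsythe), switchable
  to mean; the variant used by the original analysis environment cannot
  be pinned down, so both are exposed. Median-centered Levene is
  conservative below ~20 observations per group.
* Welch's ANOVA weights groups by `n_i/s_i²`; df₂ by Welch–Satterthwaite.
* Games–Howell: pairwise Welch t with pairwise df, p-values from the
  studentized-range distribution at `q = |t|·√2` with the full number of
  groups (`scipy.stats.studentized_range`).
* One-way ANOVA is the classical equal-variance F test, used for body
  lengths.

All p-values are reported raw; Games–Howell is the only multiplicity
handling. Zero-variance groups raise rather than returning NaN.

## Escape models

One model per taxon × response (FID, distance fled into open water,
distance fled to refuge; cm). Records with body length ≥ 25 cm are
excluded (too large to be plausible prey of the 45-cm model predator),
and distance models keep only records of the matching escape category.

Design: one coefficient per observed species × site cell (cell-means
coding), plus z-scored body length and group size. Starting distance
enters, by default, as a third standardized population-level covariate;
a config option instead bins it into 10-cm classes used as a second
varying-intercept factor. Both encode "account for the known influence
of starting distance" — a continuous covariate cannot be a varying
intercept verbatim. Observer is always a varying-intercept factor.

Priors: Normal(0, 10) on all population-level coefficients;
half-Student-t(3, 0, 10) on the residual and group-level standard
deviations (a standard weakly informative default; configurable).
Because the coefficient prior is centered at zero while responses live
at 15–40 cm, the response is mean-centered before sampling and the
center added back to the cell-mean coefficients afterwards — the usual
centered-intercept practice; without it the grand level drifts into the
observer intercepts, whose scale prior penalizes it less than twelve
cell coefficients would be penalized.

Sampling: a purpose-built Gibbs sampler (`bayes_linear.sample_lmm`).
Fixed effects and varying intercepts have conjugate Gaussian full
conditionals; the residual variance uses the inverse-gamma mixture form
of the half-t prior. Two refinements matter with only two observers:

1. each group variance is updated by a univariate slice sampler on its
   log with the intercepts integrated out analytically, removing the
   funnel between a scale and its few effects;
2. a translation move resamples the flat direction between the cell
   coefficients and each intercept batch from its exact Gaussian
   conditional.

Defaults are 4 chains × 3,000 sweeps with 1,000 warmup (8,000 retained
draws). Convergence gate: rank-normalized R-hat ≤ 1.01 and bulk ESS >
1,000 for every reported parameter (arviz); a fit that fails the gate is
flagged and refuses to produce contrasts. Empty species × site cells are
absent from the design and from contrast enumeration, with a logged
warning, rather than extrapolated.

Contrasts: per draw, the expected response for a species at a site with
covariates at their means (z = 0) and grouping terms at their zero
population mean is the cell coefficient, so a site contrast is the
difference of two cell-coefficient draws. Summaries are the posterior
mean and the 89% HPDI (coefficient tables use equal-tailed 89% CrIs);
the significance flag is exactly "interval excludes zero" — no p-values.
The Gaussian likelihood is not truncated, matching the stated modeling
choice, so posterior-predictive draws can be negative near zero.

The rugosity regressions (`structure_regression`) fit transect-level
field of view or 10-cm refuge density on rugosity with the same priors
and chain settings; the predictor is centered during sampling and the
intercept mapped back to the raw origin. The pipeline only models refuge
density against behavior when the comparison stage found a site
difference in it, mirroring the analysis logic; the decision is data-
dependent, not hard-coded.

## Synthetic data

`make_surface` builds a smoothed Gaussian random field: white noise
convolved with a Gaussian kernel of the stated correlation length
(default 0.5 m), rescaled so the elevation standard deviation equals
`relief_amplitude`, plus optional deterministic Gaussian ridges across
the transect. This gives independent control of overall relief
(rugosity) and sight-line obstruction (field of view), so the two
metrics can be decoupled in tests — deliberately, since they are only
weakly associated in real reefs. `carve_pits` subtracts non-overlapping
spherical-cap depressions and returns an exact ledger of centers, radii
and depths; on a flat base the refuge module must recover the ledger
exactly, on rough bases agreement is asserted within a stated tolerance
(roughness can create or merge depressions).

`make_study_layout` generates the field sampling design: 3 sites ×
12 transects of 25 m × 2 m at 3 cm/pixel ("study" preset; 600 m² of
reef per site), with per-site relief and ridge parameters giving one
high-relief site, one visually open site, and one intermediate. The
"desk" preset shrinks transects to 5 m × 2 m for fast runs; tests use
desk-scale surfaces so the default suite completes in minutes on one
CPU. The returned manifest is JSON-serializable and fully reconstructs
the layout.

`make_behavior_table` draws flight experiments with the study's design:
10 species in 3 taxa across 3 sites; body length uniform on 3–24 cm,
group size uniform on 1–10, starting distance uniform on 70–300 cm;
responses are species × site cell means plus covariate slopes (per sd of
the generating distribution) plus observer offsets plus Gaussian noise.
Escape categories are drawn at taxon-level frequencies whose dominant
categories match the observed study values (damselfish fled to refuge
65.1%, parrotfish fled to open water 80.3%, wrasse 86.6%); the minor-
category split is a plausible invention, as only the dominant shares are
reported. Life stages follow the observed skew (damselfish almost all
adult, the others almost all juvenile). The generator does not emulate:
site-dependent category frequencies, covariate–site interactions,
non-Gaussian (e.g. right-skewed or truncated) response noise, or any
spatial structure within a site. Passing recovery and calibration tests
therefore demonstrates correctness of the estimation machinery under the
generating model, not robustness to real-data pathologies.

## Reproducibility

Every stochastic operation takes a seed or `numpy` Generator; the
pipeline derives per-stage substreams from one master seed via
`SeedSequence.spawn`, and each run writes a manifest with the config,
seeds and package version. Identical seeds give bit-identical draws,
placements and tables.

## Known limitations

* 2.5D rasters cannot represent overhangs; refuge density undercounts.
* The FOV protocol is strictly 2D along a cross-section, not a full
  3D viewshed.
* Gaussian likelihoods on nonnegative distances are untruncated.
* Median-centered Levene is conservative at small group sizes.
* The synthetic generator's minor escape-category frequencies and the
  site-level surface parameters are plausible constructions, not
  estimates.
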