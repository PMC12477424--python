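# reefscape

Quantifies the three-dimensional structure of coral-reef habitat from
digital elevation models (DEMs) and asks how that structure relates to the
anti-predator behavior of reef fish.

The package is aimed at behavioral and spatial ecologists who have
photogrammetry-derived DEMs of reef transects (~3 cm/pixel, e.g.
25 m × 2 m strips) and flight-experiment tables (flight initiation
distance, distance fled, escape category per approach), and want the full
chain from raster to posterior contrast in one tested, reproducible
pipeline. A synthetic-data module generates reef surfaces and behavioral
tables with known ground truth, so every stage can be exercised and
validated without any field data.

## The metrics and models

**Field of view (FOV).** Along a random 10-m cross-section of the DEM, an
eye point sits 2 cm above the substrate. At each 0.5-m station, looking
toward the section center (both ways at the midpoint — 22 sight lines per
section), the steepest elevation angle θ* to any terrain point within a
1.8-m reach is found, and

    fov = (90° − clamp(θ*, 0°, 90°)) / 90°  ∈ [0, 1],

so 1 is a fully open sight line and 0 a fully obstructed one. The 22
values are averaged into one transect value.

**Refuge density.** A cell of a 1-m² quadrat is flagged when it lies at
least a threshold depth (5 / 10 / 15 cm) below the mean elevation of the
0.5-m square window centered on it. Flagged cells are grouped into
connected components ("hidey holes"); density is components per m².

**Planar rugosity.** `1 − planar_area / surface_area_3D`, with the 3D
area from a two-triangle-per-cell triangulation of the DEM: 0 for a flat
horizontal surface, approaching 1 for extremely convoluted ones.

**Site comparisons.** Levene's test (Brown–Forsythe), Welch's
heteroscedastic ANOVA with Welch–Satterthwaite df, Games–Howell pairwise
post hocs (studentized-range distribution), and classical one-way ANOVA
for body sizes.

**Escape models.** Per taxon (damselfish, parrotfish, wrasse), a Gaussian
mixed-effects model of FID / distance fled / distance to refuge with a
species × site cell-mean structure, standardized body-length and
group-size covariates, a starting-distance adjustment, and observer
varying intercepts. Priors are Normal(0, 10) on coefficients and
half-Student-t(3, 0, 10) on standard deviations; inference is by a
purpose-built Gibbs sampler (4 chains × 3,000 sweeps, 1,000 warmup) with
an R-hat ≤ 1.01 / ESS > 1,000 convergence gate. Site contrasts are
posterior differences of cell means at covariate means, summarized by
89% highest-posterior-density intervals; an effect is "significant" when
the interval excludes zero.

## Worked example

```python
import numpy as np
from reefscape import (
    SurfaceSpec, make_surface, carve_pits, transect_fov, planar_rugosity,
    quadrat_refuge_densities, FovConfig, RefugeConfig,
)

spec = SurfaceSpec(length=25, width=2, relief_amplitude=0.12,
                   ridges=((6.0, 0.4, 0.25), (17.5, 0.3, 0.2)), seed=42)
dem = make_surface(spec)
dem, ledger = carve_pits(dem, 12, (0.06, 0.2), (0.05, 0.1),
                         np.random.default_rng(1))

fov, profile = transect_fov(dem, FovConfig(), np.random.default_rng(7))
rug = planar_rugosity(dem)
dens = quadrat_refuge_densities(dem, RefugeConfig(),
                                rng=np.random.default_rng(7))
```

prints, via the obvious formatting:

```
fov          : 0.929  (cross-section at offset 9.37 m)
rugosity     : 0.048  (planar 49.4 m2, 3D 51.9 m2)
densities/m2 : 0.77 (5 cm), 0.51 (10 cm), 0.51 (15 cm)
```

— a gently rough surface with two ridges is mostly open (fov near 1),
nearly smooth at the 25-m scale, and the carved pits appear as sub-1/m²
refuge densities (deep pits count at every threshold, shallow ones only
at 5 cm; `ledger` holds the exact ground truth).

Fitting an escape model to a synthetic damselfish table generated with a
built-in +10 cm FID offset at one site:

```python
from reefscape import ModelSpec, fit_escape_model, site_contrasts
from reefscape.simulate import example_effect_spec, make_behavior_table

gen = example_effect_spec(site_effect_cm=10.0,
                          effect_species="Stegastes adustus", seed=11)
fit = fit_escape_model(make_behavior_table(gen),
                       ModelSpec(response="fid", taxon="damselfish"), seed=5)
for con in site_contrasts(fit, "Stegastes adustus"):
    print(con.site_pair, con.estimate_cm, con.hpdi_89, con.significant)
```

```
converged: True  n = 240
  Coral View - Little Bight  -1.14 cm  89% HPDI [ -3.74,   1.41]  ns
  Coral View - Sturch Bank   -8.88 cm  89% HPDI [-11.46,  -6.32]  significant
Little Bight - Sturch Bank   -7.73 cm  89% HPDI [-10.42,  -5.24]  significant
```

The generating +10 cm offset at Sturch Bank is recovered (−8.88 cm with
the truth −10 inside the 89% HPDI), and the null pair is correctly
non-significant.

## Command line

```sh
reefscape simulate --preset desk --seed 0 --out sim/      # synthetic DEMs + behavior.csv
reefscape fov --dem sim/Coral_View_t00.tif --seed 1
reefscape refuge --dem sim/Coral_View_t00.tif --thresholds 0.05,0.10,0.15
reefscape rugosity --dem sim/Coral_View_t00.tif
reefscape compare-sites --metrics-csv metrics.csv
reefscape fit --behavior-csv sim/behavior.csv --taxon damselfish --response fid --seed 2
reefscape run-all --preset desk --seed 0 --out results/
```

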