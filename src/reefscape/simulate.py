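"""Synthetic reef surfaces and behavioral tables with known ground truth.

Surfaces are smoothed Gaussian random fields (white noise convolved with a
Gaussian kernel of a chosen correlation length, rescaled to a target relief
amplitude) with optional deterministic ridges and carved pits of exactly
known position, radius and depth — so the field-of-view, refuge and
rugosity metrics can be checked against construction.  Behavioral tables
follow the flight-experiment design: species x site cell means, covariate
slopes, observer offsets and Gaussian noise, with escape categories drawn
at taxon-level frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import DEMGrid

__all__ = [
    "SurfaceSpec",
    "Pit",
    "PitLedger",
    "EffectSpec",
    "SPECIES_TAXA",
    "SITES",
    "ESCAPE_CATEGORIES",
    "TAXON_ESCAPE_PROBS",
    "make_surface",
    "carve_pits",
    "make_study_layout",
    "make_behavior_table",
    "example_effect_spec",
]

#: the ten study species and their taxa
SPECIES_TAXA = {
    "Halichoeres garnoti": "wrasse",
    "Halichoeres maculipinna": "wrasse",
    "Scarus iseri": "parrotfish",
    "Scarus taeniopterus": "parrotfish",
    "Sparisoma aurofrenatum": "parrotfish",
    "Sparisoma viride": "parrotfish",
    "Stegastes adustus": "damselfish",
    "Stegastes diencaeus": "damselfish",
    "Stegastes paritus": "damselfish",
    "Stegastes planifrons": "damselfish",
}

SITES = ("Coral View", "Little Bight", "Sturch Bank")

ESCAPE_CATEGORIES = ("fled_open", "fled_refuge", "evade", "none")

#: taxon-level escape-category frequencies; the dominant category of each
#: taxon matches the observed study frequencies (damselfish fled to refuge
#: 65.1% of the time, parrotfish fled to open water 80.3%, wrasse 86.6%);
#: the remaining mass is split plausibly among the minor categories.
TAXON_ESCAPE_PROBS = {
    "damselfish": {"fled_open": 0.149, "fled_refuge": 0.651, "evade": 0.12, "none": 0.08},
    "parrotfish": {"fled_open": 0.803, "fled_refuge": 0.097, "evade": 0.06, "none": 0.04},
    "wrasse": {"fled_open": 0.866, "fled_refuge": 0.074, "evade": 0.04, "none": 0.02},
}

#: covariate sampling ranges mirroring the field protocol: estimated total
#: length 3-24 cm (larger fish were excluded), monospecific group size 1-10,
#: predator starting distance 0.7-3 m.
BODY_LENGTH_RANGE = (3.0, 24.0)
GROUP_SIZE_RANGE = (1, 10)
START_DISTANCE_RANGE = (70.0, 300.0)


@dataclass(frozen=True)
class SurfaceSpec:
    """Parameters of one synthetic transect surface.

    relief_amplitude is the standard deviation of the random relief in m;
    correlation_length sets the Gaussian smoothing kernel (m).  Ridges are
    (position_m, height_m, width_m) Gaussian walls across the transect.
    """

    length: float = 25.0
    width: float = 2.0
    cell_size: float = 0.03
    relief_amplitude: float = 0.10
    correlation_length: float = 0.5
    ridges: tuple[tuple[float, float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0 or self.cell_size <= 0:
            raise ValueError("degenerate surface dimensions")
        if self.relief_amplitude < 0 or self.correlation_length <= 0:
            raise ValueError("invalid relief parameters")


@dataclass(frozen=True)
class Pit:
    center: tuple[float, float]
    radius: float
    depth: float


@dataclass
class PitLedger:
    """Exact ground truth for carved depressions."""

    pits: list[Pit] = field(default_factory=list)

    def expected_count(self, threshold: float) -> int:
        """Pits at least ``threshold`` deep (exact on a flat base surface)."""
        return sum(1 for p in self.pits if p.depth >= threshold)

    def to_dict(self) -> dict:
        return {"pits": [asdict(p) for p in self.pits]}


def make_surface(spec: SurfaceSpec) -> DEMGrid:
    """Generate a smoothed-Gaussian-random-field reef surface.

    Deterministic under ``spec.seed``.  Zero relief amplitude with no
    ridges yields an exactly flat grid.
    """
    c = spec.cell_size
    ncols = int(round(spec.length / c))
    nrows = int(round(spec.width / c))
    if nrows < 2 or ncols < 2:
        raise ValueError("surface smaller than 2x2 cells")
    rng = np.random.default_rng(spec.seed)
    if spec.relief_amplitude > 0:
        noise = rng.standard_normal((nrows, ncols))
        sigma = spec.correlation_length / c
        smooth = ndimage.gaussian_filter(noise, sigma, mode="reflect")
        sd = smooth.std()
        z = smooth * (spec.relief_amplitude / sd) if sd > 0 else np.zeros_like(smooth)
    else:
        z = np.zeros((nrows, ncols))
    if spec.ridges:
        x = (np.arange(ncols) + 0.5) * c
        for pos, height, width in spec.ridges:
            z = z + height * np.exp(-0.5 * ((x - pos) / width) ** 2)[None, :]
    return DEMGrid(z, c)


def carve_pits(
    grid: DEMGrid,
    n: int,
    depth_range: tuple[float, float],
    radius_range: tuple[float, float],
    rng: np.random.Generator | None = None,
    margin: float = 0.3,
    max_tries: int = 10_000,
) -> tuple[DEMGrid, PitLedger]:
    """Subtract ``n`` non-overlapping spherical-cap depressions.

    Pits are placed by rejection sampling with at least ``margin`` m from
    the boundary and a small clearance between rims; the returned ledger
    records each pit exactly.  Raises when placement is infeasible.
    """
    rng = np.random.default_rng(rng)
    c = grid.cell_size
    nrows, ncols = grid.shape
    xs = (np.arange(ncols) + 0.5) * c + grid.origin[0]
    ys = (np.arange(nrows) + 0.5) * c + grid.origin[1]
    z = grid.elevations.copy()
    ledger = PitLedger()
    placed: list[Pit] = []
    tries = 0
    while len(placed) < n:
        if tries >= max_tries:
            raise ValueError(f"could not place {n} non-overlapping pits")
        tries += 1
        r = float(rng.uniform(*radius_range))
        d = float(rng.uniform(*depth_range))
        lo_x, hi_x = grid.origin[0] + margin + r, grid.origin[0] + grid.extent_x - margin - r
        lo_y, hi_y = grid.origin[1] + margin + r, grid.origin[1] + grid.extent_y - margin - r
        if lo_x >= hi_x or lo_y >= hi_y:
            raise ValueError("grid too small for requested pit radius and margin")
        cx = float(rng.uniform(lo_x, hi_x))
        cy = float(rng.uniform(lo_y, hi_y))
        if any(
            math.hypot(cx - p.center[0], cy - p.center[1]) < r + p.radius + 2 * c
            for p in placed
        ):
            continue
        placed.append(Pit((cx, cy), r, d))
    for pit in placed:
        r, d = pit.radius, pit.depth
        big_r = (r * r + d * d) / (2 * d)  # sphere radius of the cap
        dist2 = (xs[None, :] - pit.center[0]) ** 2 + (ys[:, None] - pit.center[1]) ** 2
        inside = dist2 <= r * r
        depression = np.zeros_like(z)
        depression[inside] = np.sqrt(big_r**2 - dist2[inside]) - (big_r - d)
        z -= depression
        ledger.pits.append(pit)
    return DEMGrid(z, c, grid.origin), ledger


#: per-site surface parameters: one high-relief site, one visually open
#: low-ridge site, one intermediate — mirroring three reefs chosen for
#: contrasting structural complexity.
SITE_SURFACE_PARAMS = {
    "Coral View": {"relief_amplitude": 0.12, "n_ridges": 3, "ridge_height": 0.35},
    "Little Bight": {"relief_amplitude": 0.16, "n_ridges": 5, "ridge_height": 0.45},
    "Sturch Bank": {"relief_amplitude": 0.07, "n_ridges": 1, "ridge_height": 0.20},
}


def make_study_layout(
    n_sites: int = 3,
    n_transects: int = 12,
    preset: str = "study",
    seed: int = 0,
    cell_size: float = 0.03,
) -> tuple[dict[str, list[DEMGrid]], dict]:
    """Generate the full sampling layout: transect DEMs per site.

    ``preset='study'`` gives 25 m x 2 m transects (12 per site = 600 m^2 of
    reef per site); ``preset='desk'`` gives 5 m x 2 m transects for fast
    runs.  Sites differ in relief amplitude and ridge structure per
    ``SITE_SURFACE_PARAMS``.  Returns ``(grids_by_site, manifest)`` where
    the manifest is JSON-serializable and fully reconstructs the layout.
    """
    if preset not in {"study", "desk"}:
        raise ValueError("preset must be 'study' or 'desk'")
    length = 25.0 if preset == "study" else 5.0
    sites = list(SITES)[:n_sites]
    ss = np.random.SeedSequence(seed)
    site_seeds = ss.spawn(len(sites))
    grids: dict[str, list[DEMGrid]] = {}
    manifest: dict = {
        "preset": preset, "seed": seed, "length_m": length, "width_m": 2.0,
        "cell_size_m": cell_size, "n_transects": n_transects, "sites": {},
    }
    for site, sseq in zip(sites, site_seeds):
        params = SITE_SURFACE_PARAMS[site]
        rng = np.random.default_rng(sseq)
        site_grids = []
        site_manifest = []
        for t in range(n_transects):
            tseed = int(rng.integers(0, 2**31 - 1))
            ridge_rng = np.random.default_rng(tseed)
            ridges = tuple(
                (
                    float(ridge_rng.uniform(1.0, length - 1.0)),
                    float(ridge_rng.uniform(0.5, 1.0) * params["ridge_height"]),
                    float(ridge_rng.uniform(0.15, 0.4)),
                )
                for _ in range(params["n_ridges"])
            )
            spec = SurfaceSpec(
                length=length, width=2.0, cell_size=cell_size,
                relief_amplitude=params["relief_amplitude"],
                ridges=ridges, seed=tseed,
            )
            site_grids.append(make_surface(spec))
            site_manifest.append(
                {
                    "transect": t, "seed": tseed,
                    "relief_amplitude": params["relief_amplitude"],
                    "ridges": [list(r) for r in ridges],
                }
            )
        grids[site] = site_grids
        manifest["sites"][site] = site_manifest
    return grids, manifest


@dataclass(frozen=True)
class EffectSpec:
    """Known effect structure for a synthetic behavioral table.

    ``cell_means`` maps (species, site) to the mean of the target response
    in cm; slopes are cm per standard deviation of the generating covariate
    distribution; ``observer_offsets`` are additive cm shifts per observer.
    """

    species: tuple[str, ...]
    sites: tuple[str, ...] = SITES
    response: str = "fid"
    cell_means: dict[tuple[str, str], float] = field(default_factory=dict)
    body_length_slope: float = 0.0
    group_size_slope: float = 0.0
    start_distance_slope: float = 0.0
    observer_offsets: dict[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 0.0}
    )
    residual_sd: float = 5.0
    n_per_cell: int = 20
    escape_probs: dict[str, dict[str, float]] = field(
        default_factory=lambda: TAXON_ESCAPE_PROBS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sd < 0 or self.n_per_cell < 1:
            raise ValueError("residual_sd >= 0 and n_per_cell >= 1 required")
        for sp in self.species:
            if sp not in SPECIES_TAXA:
                raise ValueError(f"unknown species {sp!r}")


def example_effect_spec(
    taxon: str = "damselfish",
    site_effect_cm: float = 0.0,
    effect_species: str | None = None,
    effect_site: str = "Sturch Bank",
    seed: int = 0,
    **overrides,
) -> EffectSpec:
    """A ready-made effect structure for one taxon.

    Baseline cell means vary by species (15-25 cm); ``site_effect_cm`` adds
    a known offset for one species at one site — the ground truth for
    contrast-recovery checks.
    """
    species = tuple(sp for sp, t in SPECIES_TAXA.items() if t == taxon)
    if effect_species is None:
        effect_species = species[0]
    base = {sp: 15.0 + 3.0 * i for i, sp in enumerate(species)}
    cell_means = {
        (sp, site): base[sp] + (site_effect_cm if sp == effect_species and site == effect_site else 0.0)
        for sp in species
        for site in SITES
    }
    kwargs = dict(
        species=species, cell_means=cell_means,
        body_length_slope=2.0, group_size_slope=-1.0, start_distance_slope=3.0,
        observer_offsets={"A": 1.0, "B": -1.0}, residual_sd=5.0,
        n_per_cell=20, seed=seed,
    )
    kwargs.update(overrides)
    return EffectSpec(**kwargs)


def _uniform_moments(lo: float, hi: float) -> tuple[float, float]:
    return (lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0)


def make_behavior_table(spec: EffectSpec) -> pd.DataFrame:
    """Generate a flight-experiment table with known effect structure.

    The target response equals cell mean + slopes x z-scored covariates +
    observer offset + Gaussian noise, where z-scores use the theoretical
    moments of the generating covariate distributions.  In the noiseless,
    zero-slope limit every response equals its cell mean exactly.  The two
    non-target distance columns are filled with unstructured plausible
    values so the table is schema-complete.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    bl_mu, bl_sd = _uniform_moments(*BODY_LENGTH_RANGE)
    gs_lo, gs_hi = GROUP_SIZE_RANGE
    gs_mu = (gs_lo + gs_hi) / 2.0
    gs_sd = math.sqrt(((gs_hi - gs_lo + 1) ** 2 - 1) / 12.0)
    sd_mu, sd_sd = _uniform_moments(*START_DISTANCE_RANGE)
    observers = sorted(spec.observer_offsets)
    for sp in spec.species:
        taxon = SPECIES_TAXA[sp]
        probs = spec.escape_probs[taxon]
        pvec = np.array([probs[c] for c in ESCAPE_CATEGORIES])
        pvec = pvec / pvec.sum()
        for site in spec.sites:
            mean = spec.cell_means.get((sp, site), 20.0)
            n = spec.n_per_cell
            body = rng.uniform(*BODY_LENGTH_RANGE, size=n)
            group = rng.integers(gs_lo, gs_hi + 1, size=n)
            start = rng.uniform(*START_DISTANCE_RANGE, size=n)
            obs = rng.choice(observers, size=n)
            cats = rng.choice(ESCAPE_CATEGORIES, size=n, p=pvec)
            stage = rng.choice(
                ["adult", "juvenile"],
                size=n,
                p=[0.966, 0.034] if taxon == "damselfish" else [0.03, 0.97],
            )
            noise = rng.normal(0.0, spec.residual_sd, size=n) if spec.residual_sd else np.zeros(n)
            response = (
                mean
                + spec.body_length_slope * (body - bl_mu) / bl_sd
                + spec.group_size_slope * (group - gs_mu) / gs_sd
                + spec.start_distance_slope * (start - sd_mu) / sd_sd
                + np.array([spec.observer_offsets[o] for o in obs])
                + noise
            )
            # filler values for the non-target distance columns
            open_fill = rng.uniform(20.0, 120.0, size=n)
            refuge_fill = rng.uniform(5.0, 60.0, size=n)
            for i in range(n):
                fid = response[i] if spec.response == "fid" else float(rng.uniform(5.0, 60.0))
                fid = max(fid, 0.0)
                d_open = (
                    response[i] if spec.response == "distance_open" else open_fill[i]
                ) if cats[i] == "fled_open" else np.nan
                d_ref = (
                    response[i] if spec.response == "distance_refuge" else refuge_fill[i]
                ) if cats[i] == "fled_refuge" else np.nan
                rows.append(
                    {
                        "species": sp,
                        "taxon": taxon,
                        "site": site,
                        "escape_category": cats[i],
                        "fid_cm": fid,
                        "distance_open_cm": d_open,
                        "distance_refuge_cm": d_ref,
                        "start_distance_cm": max(start[i], fid),
                        "body_length_cm": body[i],
                        "group_size": int(group[i]),
                        "life_stage": stage[i],
                        "observer": obs[i],
                    }
                )
    return pd.DataFrame(rows)
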