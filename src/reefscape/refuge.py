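"""Refuge ("hidey hole") detection in DEM quadrats.

A cell is part of a potential refuge when it lies at least a threshold
depth below the mean elevation of a square moving window centered on it.
Flagged cells are grouped into connected components; refuge density is the
component count per square meter of valid quadrat area.  Thresholds of
5, 10 and 15 cm target holes on the scale of small reef fish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import DEMGrid, random_quadrats

__all__ = [
    "RefugeConfig",
    "RefugeComponent",
    "RefugeSet",
    "depression_mask",
    "local_mean_elevation",
    "label_refuges",
    "quadrat_refuge_densities",
]


@dataclass(frozen=True)
class RefugeConfig:
    """Depression-detection parameters.

    depth_thresholds: depths below the local mean that qualify, m, ascending.
    window_size: side of the square local-mean window, m (>= 3 cells).
    connectivity: 4 (edge) or 8 (edge+corner) neighborhood for grouping.
    min_area: smallest component, in cells, counted as a refuge.
    """

    depth_thresholds: tuple[float, ...] = (0.05, 0.10, 0.15)
    window_size: float = 0.5
    connectivity: int = 8
    min_area: int = 1

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.depth_thresholds):
            raise ValueError("thresholds must be positive")
        if list(self.depth_thresholds) != sorted(self.depth_thresholds):
            raise ValueError("thresholds must be ascending")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")

    def window_cells(self, cell_size: float) -> int:
        half = max(1, int(round(self.window_size / cell_size)) // 2)
        return 2 * half + 1


@dataclass(frozen=True)
class RefugeComponent:
    label: int
    cell_count: int
    max_depth: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class RefugeSet:
    threshold: float
    components: tuple[RefugeComponent, ...]
    count: int
    density: float


def _box_sums(values: np.ndarray, win: int) -> np.ndarray:
    """Sums over a centered win x win window, truncated at the edges."""
    half = win // 2
    padded = np.zeros((values.shape[0] + 1, values.shape[1] + 1))
    np.cumsum(np.cumsum(values, axis=0), axis=1, out=padded[1:, 1:])
    n0, n1 = values.shape
    i = np.arange(n0)[:, None]
    j = np.arange(n1)[None, :]
    top = np.clip(i - half, 0, n0)
    bot = np.clip(i + half + 1, 0, n0)
    left = np.clip(j - half, 0, n1)
    right = np.clip(j + half + 1, 0, n1)
    return (
        padded[bot, right] - padded[top, right] - padded[bot, left] + padded[top, left]
    )


def local_mean_elevation(grid: DEMGrid, cfg: RefugeConfig = RefugeConfig()) -> np.ndarray:
    """Mean elevation over the centered window, valid cells only.

    Edge cells use the truncated window.  Cells whose window holds no valid
    neighbor come back NaN.
    """
    win = cfg.window_cells(grid.cell_size)
    if min(grid.shape) < 3:
        raise ValueError("grid smaller than the minimum 3-cell window")
    valid = ~grid.nodata_mask
    filled = np.where(valid, grid.elevations, 0.0)
    sums = _box_sums(filled, win)
    counts = _box_sums(valid.astype(float), win)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / counts, np.nan)
    return means


def depression_mask(
    grid: DEMGrid, threshold: float, cfg: RefugeConfig = RefugeConfig()
) -> np.ndarray:
    """Cells at least ``threshold`` m below their local mean elevation."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    means = local_mean_elevation(grid, cfg)
    valid = ~grid.nodata_mask
    depth = means - grid.elevations
    return valid & np.isfinite(depth) & (depth >= threshold)


def label_refuges(
    mask: np.ndarray, grid: DEMGrid, cfg: RefugeConfig = RefugeConfig(),
    threshold: float = float("nan"),
) -> RefugeSet:
    """Group flagged cells into contiguous refuges and summarize them."""
    if mask.shape != grid.shape:
        raise ValueError("mask does not align with grid")
    structure = (
        np.ones((3, 3), dtype=bool)
        if cfg.connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    labels, n_raw = ndimage.label(mask, structure=structure)
    depth = local_mean_elevation(grid, cfg) - grid.elevations
    comps: list[RefugeComponent] = []
    if n_raw:
        idx = np.arange(1, n_raw + 1)
        areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
        max_depths = ndimage.labeled_comprehension(
            depth, labels, idx, np.max, float, np.nan
        )
        centroids = ndimage.center_of_mass(mask, labels, idx)
        c = grid.cell_size
        for lab, area, dep, (ci, cj) in zip(idx, areas, max_depths, centroids):
            if area < cfg.min_area:
                continue
            centroid = (
                grid.origin[0] + (cj + 0.5) * c,
                grid.origin[1] + (ci + 0.5) * c,
            )
            comps.append(RefugeComponent(int(lab), int(area), float(dep), centroid))
    density = len(comps) / grid.valid_area_m2
    return RefugeSet(threshold, tuple(comps), len(comps), density)


def quadrat_refuge_densities(
    grid: DEMGrid,
    cfg: RefugeConfig = RefugeConfig(),
    n_quadrats: int = 4,
    rng: np.random.Generator | None = None,
    quadrat_size: float = 1.0,
):
    """Refuge counts and densities over random quadrats of a transect.

    Returns a tidy DataFrame with one row per quadrat x threshold:
    (quadrat, threshold_m, count, density_per_m2, quadrat_x, quadrat_y).
    """
    import pandas as pd

    quadrats = random_quadrats(grid, n=n_quadrats, size=quadrat_size, rng=rng)
    rows = []
    for q_idx, quad in enumerate(quadrats):
        for thr in cfg.depth_thresholds:
            refuges = label_refuges(depression_mask(quad, thr, cfg), quad, cfg, thr)
            rows.append(
                {
                    "quadrat": q_idx,
                    "threshold_m": thr,
                    "count": refuges.count,
                    "density_per_m2": refuges.density,
                    "quadrat_x": quad.origin[0],
                    "quadrat_y": quad.origin[1],
                }
            )
    return pd.DataFrame(rows)
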