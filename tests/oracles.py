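"""Independent brute-force oracles used to check the implementation.

Everything here is written as plainly as possible — per-station loops,
per-cell window means, explicit cross products, breadth-first flood fill —
and deliberately shares no code with the package internals it checks.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def bilinear_point(grid, x: float, y: float) -> float:
    """Single-point bilinear interpolation from the four cell centers."""
    c = grid.cell_size
    u = (x - grid.origin[0]) / c - 0.5
    v = (y - grid.origin[1]) / c - 0.5
    nrows, ncols = grid.shape
    u = min(max(u, 0.0), ncols - 1.0)
    v = min(max(v, 0.0), nrows - 1.0)
    j0 = min(int(math.floor(u)), ncols - 2)
    i0 = min(int(math.floor(v)), nrows - 2)
    fu, fv = u - j0, v - i0
    z = grid.elevations
    return (
        z[i0, j0] * (1 - fu) * (1 - fv)
        + z[i0, j0 + 1] * fu * (1 - fv)
        + z[i0 + 1, j0] * (1 - fu) * fv
        + z[i0 + 1, j0 + 1] * fu * fv
    )


def max_sight_angle(profile, station: float, direction: int, eye_height: float,
                    reach: float) -> float:
    """Exhaustive per-sample-point maximization of the elevation angle."""
    z_eye = float(np.interp(station, profile.distances, profile.elevations)) + eye_height
    best = -math.inf
    for d, z in zip(profile.distances, profile.elevations):
        dx = (d - station) * direction
        if dx <= 1e-12:
            continue
        if math.hypot(dx, z - z_eye) > reach + 1e-12:
            continue
        best = max(best, math.degrees(math.atan2(z - z_eye, dx)))
    return best


def window_mean_mask(grid, threshold: float, window_size: float) -> np.ndarray:
    """Per-cell truncated-window mean and depth flagging, direct loops."""
    c = grid.cell_size
    half = max(1, int(round(window_size / c)) // 2)
    z = grid.elevations
    nrows, ncols = z.shape
    mask = np.zeros((nrows, ncols), dtype=bool)
    for i in range(nrows):
        for j in range(ncols):
            if not np.isfinite(z[i, j]):
                continue
            win = z[max(0, i - half): i + half + 1, max(0, j - half): j + half + 1]
            vals = win[np.isfinite(win)]
            if vals.size == 0:
                continue
            mask[i, j] = vals.mean() - z[i, j] >= threshold
    return mask


def flood_fill_count(mask: np.ndarray, connectivity: int = 8, min_area: int = 1) -> int:
    """Connected-component count by breadth-first flood fill."""
    if connectivity == 8:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    nrows, ncols = mask.shape
    count = 0
    for i in range(nrows):
        for j in range(ncols):
            if not mask[i, j] or seen[i, j]:
                continue
            area = 0
            queue = deque([(i, j)])
            seen[i, j] = True
            while queue:
                ci, cj = queue.popleft()
                area += 1
                for di, dj in steps:
                    ni, nj = ci + di, cj + dj
                    if 0 <= ni < nrows and 0 <= nj < ncols and mask[ni, nj] and not seen[ni, nj]:
                        seen[ni, nj] = True
                        queue.append((ni, nj))
            if area >= min_area:
                count += 1
    return count


def triangle_surface_area(grid) -> float:
    """3D area by explicit per-triangle cross products (NW-SE diagonal)."""
    z = grid.elevations
    c = grid.cell_size
    nrows, ncols = z.shape
    total = 0.0
    for i in range(nrows - 1):
        for j in range(ncols - 1):
            quad = z[i: i + 2, j: j + 2]
            if not np.all(np.isfinite(quad)):
                continue
            sw = np.array([(j + 0.5) * c, (i + 0.5) * c, z[i, j]])
            se = np.array([(j + 1.5) * c, (i + 0.5) * c, z[i, j + 1]])
            nw = np.array([(j + 0.5) * c, (i + 1.5) * c, z[i + 1, j]])
            ne = np.array([(j + 1.5) * c, (i + 1.5) * c, z[i + 1, j + 1]])
            for (a, b, d) in ((nw, sw, se), (nw, se, ne)):
                cross = np.cross(b - a, d - a)
                total += 0.5 * math.sqrt(float(cross @ cross))
    return total
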