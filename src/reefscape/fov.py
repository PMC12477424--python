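"""Field-of-view metric along DEM cross-sections.

The metric emulates a sight-line protocol at fish eye height: an eye sits
2 cm above the substrate at a station on a 10-m cross-section, and the
steepest elevation angle to any terrain point within a 1.8-m reach (the
mean predator starting distance) is found.  The field of view is the
normalized complement of that angle,

    fov = (90 deg - clamp(angle, 0, 90)) / 90,

so 1 means fully open sight lines and 0 a fully obstructed hemifield.
Stations step every 0.5 m toward the section center, the central station
looks both ways, giving 22 measurements per 10-m section that are averaged
into one transect value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import CrossSectionProfile, DEMGrid, random_cross_section

__all__ = [
    "FovConfig",
    "FovMeasurement",
    "sight_angle",
    "station_fov",
    "cross_section_fov",
    "transect_fov",
]

TOWARD_INCREASING = +1
TOWARD_DECREASING = -1


@dataclass(frozen=True)
class FovConfig:
    """Geometry of the sight-line protocol.

    eye_height: eye position above the substrate, m.
    reach: maximum Euclidean eye-to-point distance considered, m.
    station_step: spacing of measurement stations, m (must divide
        section_length).
    section_length: cross-section length, m.
    clamp_negative: treat terrain entirely below eye level as a level
        horizon (angle 0) rather than a negative angle.
    target: 'max_angle' picks the point with the steepest elevation angle
        within reach; 'max_elevation' picks the highest point within reach
        (the two coincide on monotone obstacles).
    """

    eye_height: float = 0.02
    reach: float = 1.8
    station_step: float = 0.5
    section_length: float = 10.0
    clamp_negative: bool = True
    target: str = "max_angle"

    def __post_init__(self) -> None:
        if self.eye_height < 0 or self.reach <= 0 or self.station_step <= 0:
            raise ValueError("eye_height >= 0 and reach, station_step > 0 required")
        ratio = self.section_length / self.station_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("station_step must divide section_length")
        if self.target not in {"max_angle", "max_elevation"}:
            raise ValueError("target must be 'max_angle' or 'max_elevation'")


@dataclass(frozen=True)
class FovMeasurement:
    station: float
    direction: int
    max_angle_deg: float
    fov: float


def sight_angle(
    profile: CrossSectionProfile,
    station: float,
    direction: int,
    cfg: FovConfig = FovConfig(),
) -> float:
    """Steepest terrain elevation angle (degrees) seen from a station.

    The eye sits ``cfg.eye_height`` above the substrate at the station.
    Candidate points are profile samples strictly on the ``direction`` side
    of the station whose Euclidean distance from the eye is at most
    ``cfg.reach``.  Angles are measured from the horizontal:
    ``atan((z_p - z_eye) / |x_p - x_station|)``.
    """
    if direction not in (TOWARD_INCREASING, TOWARD_DECREASING):
        raise ValueError("direction must be +1 or -1")
    z_eye = profile.elevation_at(station) + cfg.eye_height
    dx = (profile.distances - station) * direction
    dz = profile.elevations - z_eye
    cand = dx > 1e-12
    cand &= np.hypot(dx, dz) <= cfg.reach + 1e-12
    if not np.any(cand):
        raise ValueError(
            f"no profile point within reach {cfg.reach} m of station {station} m"
        )
    if cfg.target == "max_angle":
        angle = math.degrees(float(np.max(np.arctan2(dz[cand], dx[cand]))))
    else:
        k = np.flatnonzero(cand)[int(np.argmax(profile.elevations[cand]))]
        angle = math.degrees(math.atan2(dz[k], abs(dx[k])))
    if cfg.clamp_negative and angle < 0:
        angle = 0.0
    return angle


def station_fov(
    profile: CrossSectionProfile,
    station: float,
    direction: int,
    cfg: FovConfig = FovConfig(),
) -> FovMeasurement:
    """Field of view at one station: ``(90 - clamp(angle, 0, 90)) / 90``."""
    angle = sight_angle(profile, station, direction, cfg)
    fov = (90.0 - min(max(angle, 0.0), 90.0)) / 90.0
    return FovMeasurement(station, direction, angle, fov)


def cross_section_fov(
    profile: CrossSectionProfile,
    cfg: FovConfig = FovConfig(),
) -> tuple[float, list[FovMeasurement]]:
    """Mean field of view over the station grid of one cross-section.

    Stations run every ``station_step`` from 0 to ``section_length``; each
    aims toward the section center, and the central station is measured in
    both directions (22 measurements under the defaults).
    """
    if abs(profile.total_length - cfg.section_length) > 1e-6:
        raise ValueError(
            f"profile length {profile.total_length} m != section length "
            f"{cfg.section_length} m"
        )
    n = int(round(cfg.section_length / cfg.station_step))
    mid = cfg.section_length / 2.0
    measurements: list[FovMeasurement] = []
    for k in range(n + 1):
        s = k * cfg.station_step
        if abs(s - mid) < 1e-9:
            dirs = (TOWARD_INCREASING, TOWARD_DECREASING)
        elif s < mid:
            dirs = (TOWARD_INCREASING,)
        else:
            dirs = (TOWARD_DECREASING,)
        for direction in dirs:
            measurements.append(station_fov(profile, s, direction, cfg))
    mean = float(np.mean([m.fov for m in measurements]))
    return mean, measurements


def transect_fov(
    grid: DEMGrid,
    cfg: FovConfig = FovConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[float, CrossSectionProfile]:
    """One transect value: mean fov of a random 10-m cross-section.

    Returns the mean together with the profile (whose metadata logs the
    random placement) so the measurement can be recomputed exactly.
    """
    profile = random_cross_section(grid, length=cfg.section_length, rng=rng)
    mean, _ = cross_section_fov(profile, cfg)
    return mean, profile
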