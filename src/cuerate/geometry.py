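"""Spatial conversions for a shore-based whale survey.

Maps infrared-camera pixel coordinates to range and azimuth, places
detections on the globe, and computes the mean time a migrating whale
spends inside each sensor's search area.

The range calculation uses the classic elevated-observer geometry on a
spherical earth: a pixel row below the horizon gives a depression angle
via linear interpolation of the vertical field of view; adding the
horizon dip ``arccos(R/(R+h))`` gives the total depression below the
local horizontal, from which the along-surface distance follows.
Atmospheric refraction can be folded in through an effective-earth-radius
multiplier (default 1, i.e. no refraction correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

__all__ = [
    "EARTH_RADIUS_M",
    "SurveyGeometry",
    "TransitTime",
    "pixel_to_range",
    "pixel_to_azimuth",
    "range_to_pixel_row",
    "azimuth_to_pixel_col",
    "range_bearing_to_position",
    "position_to_range_bearing",
    "horizon_dip_deg",
    "camera_transit_time",
    "acoustic_transit_time",
]


class OutOfDomainError(ValueError):
    """Pixel or angle outside the geometric domain of the conversion."""


@dataclass
class SurveyGeometry:
    """Fixed geometry of the shore-based survey site.

    Defaults reflect a typical deployment: observers ~22 m above sea
    level, camera ~28 m, a narrow 6.2° x 5° infrared field of view on a
    640x480 sensor, and a hydrophone array whose along-migration extent
    is 2.28 km.  ``horizon_row_px`` is a per-deployment calibration: the
    image row on which the sea horizon sits.  ``refraction_k`` scales
    the earth radius to emulate standard atmospheric refraction
    (k ~ 7/6); the default of 1 applies no correction.
    """

    observer_position: tuple[float, float] = (36.439892, -121.922367)
    observer_height_m: float = 22.3
    camera_position: tuple[float, float] = (36.440169, -121.922058)
    camera_height_m: float = 28.1
    camera_hfov_deg: float = 6.2
    camera_vfov_deg: float = 5.0
    image_width_px: int = 640
    image_height_px: int = 480
    horizon_row_px: float = 40.0
    camera_edge_azimuths_deg: tuple[float, float] = (261.9, 268.1)
    hydrophone_positions: tuple[tuple[float, float], ...] = (
        (36.420, -121.936),  # SE
        (36.429, -121.953),  # SW
        (36.449, -121.940),  # NE
        (36.458, -121.957),  # NW
    )
    array_transit_distance_m: float = 2280.0
    earth_radius_m: float = EARTH_RADIUS_M
    refraction_k: float = 1.0

    def __post_init__(self) -> None:
        if self.observer_height_m <= 0 or self.camera_height_m <= 0:
            raise ValueError("observer/camera heights must be positive")
        if self.camera_hfov_deg <= 0 or self.camera_vfov_deg <= 0:
            raise ValueError("field-of-view angles must be positive")
        if self.array_transit_distance_m <= 0:
            raise ValueError("array transit distance must be positive")
        if len(self.hydrophone_positions) != 4:
            raise ValueError("exactly 4 hydrophone positions required")
        if self.refraction_k <= 0:
            raise ValueError("refraction multiplier must be positive")

    @property
    def effective_radius_m(self) -> float:
        return self.refraction_k * self.earth_radius_m


@dataclass(frozen=True)
class TransitTime:
    """Mean whale transit time through a sensor search area, minutes."""

    value_minutes: float
    search_area_label: str  # "acoustic" | "camera"

    def __post_init__(self) -> None:
        if self.value_minutes < 0:
            raise ValueError("transit time must be nonnegative")

    @property
    def value_days(self) -> float:
        return self.value_minutes / 1440.0

    @property
    def value_hours(self) -> float:
        return self.value_minutes / 60.0


def horizon_dip_deg(height_m: float, radius_m: float = EARTH_RADIUS_M) -> float:
    """Angular dip of the sea horizon below the local horizontal.

    For an observer at height h on a sphere of radius R the dip is
    ``arccos(R/(R+h))``; this also equals the geocentric angle subtended
    by the horizon distance.
    """
    if height_m <= 0:
        raise ValueError("height must be positive")
    return math.degrees(math.acos(radius_m / (radius_m + height_m)))


def _depression_to_surface_distance(beta_rad: float, height_m: float, radius_m: float) -> float:
    # Triangle earth-centre / observer / sea-surface target: the geocentric
    # angle gamma for a sight line depressed beta below the horizontal is
    #   gamma = beta + arcsin(((R+h)/R) cos beta) - pi/2,
    # valid from the horizon (beta = dip, gamma = dip) down to nadir.
    R = radius_m
    s = (R + height_m) / R * math.cos(beta_rad)
    if s > 1.0:
        raise OutOfDomainError("sight line passes above the horizon")
    gamma = beta_rad + math.asin(s) - math.pi / 2.0
    return R * gamma


def pixel_to_range(row_px: float, geom: SurveyGeometry) -> float:
    """Surface range (m) to a target sitting on image row ``row_px``.

    The row must lie strictly below the calibrated horizon row.  Raises
    :class:`OutOfDomainError` at or above the horizon, or if the implied
    depression angle exceeds the bottom of the vertical field of view.
    """
    if row_px >= geom.image_height_px:
        raise OutOfDomainError(f"row {row_px} outside image of height {geom.image_height_px}")
    delta_deg = (row_px - geom.horizon_row_px) * (geom.camera_vfov_deg / geom.image_height_px)
    if delta_deg <= 0:
        raise OutOfDomainError("pixel row at or above the horizon: range undefined")
    if delta_deg > geom.camera_vfov_deg:
        raise OutOfDomainError("depression angle exceeds the vertical field of view")
    R = geom.effective_radius_m
    dip_deg = horizon_dip_deg(geom.camera_height_m, R)
    beta = math.radians(delta_deg + dip_deg)
    return _depression_to_surface_distance(beta, geom.camera_height_m, R)


def pixel_to_azimuth(col_px: float, geom: SurveyGeometry) -> float:
    """True bearing (deg) of the target on image column ``col_px``.

    Linear interpolation between the calibrated azimuths of the left and
    right image edges; the interpolated span equals the horizontal FOV.
    """
    if not 0 <= col_px < geom.image_width_px:
        raise OutOfDomainError(f"column {col_px} outside image of width {geom.image_width_px}")
    left, right = geom.camera_edge_azimuths_deg
    span = (right - left) % 360.0
    frac = col_px / geom.image_width_px
    return (left + frac * span) % 360.0


def range_to_pixel_row(range_m: float, geom: SurveyGeometry) -> float:
    """Inverse of :func:`pixel_to_range`: image row for a surface range."""
    if range_m <= 0:
        raise OutOfDomainError("range must be positive")
    R = geom.effective_radius_m
    h = geom.camera_height_m
    gamma = range_m / R
    beta = math.atan2((R + h) - R * math.cos(gamma), R * math.sin(gamma))
    delta_deg = math.degrees(beta) - horizon_dip_deg(h, R)
    if delta_deg <= 0 or delta_deg > geom.camera_vfov_deg:
        raise OutOfDomainError("range outside the camera's vertical field of view")
    return geom.horizon_row_px + delta_deg / (geom.camera_vfov_deg / geom.image_height_px)


def azimuth_to_pixel_col(bearing_deg: float, geom: SurveyGeometry) -> float:
    """Inverse of :func:`pixel_to_azimuth`: image column for a true bearing."""
    left, right = geom.camera_edge_azimuths_deg
    span = (right - left) % 360.0
    frac = ((bearing_deg - left) % 360.0) / span
    if frac > 1.0:
        raise OutOfDomainError("bearing outside the horizontal field of view")
    return min(frac * geom.image_width_px, geom.image_width_px - 1e-9)


def range_bearing_to_position(
    origin: tuple[float, float],
    range_m: float,
    bearing_deg: float,
    radius_m: float = EARTH_RADIUS_M,
) -> tuple[float, float]:
    """Forward geodesic on a spherical earth: (lat, lon) at the given
    surface range and true bearing from ``origin`` (decimal degrees)."""
    if range_m < 0:
        raise ValueError("range must be nonnegative")
    lat1 = math.radians(origin[0])
    lon1 = math.radians(origin[1])
    theta = math.radians(bearing_deg)
    delta = range_m / radius_m
    lat2 = math.asin(
        math.sin(lat1) * math.cos(delta) + math.cos(lat1) * math.sin(delta) * math.cos(theta)
    )
    lon2 = lon1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(lat1),
        math.cos(delta) - math.sin(lat1) * math.sin(lat2),
    )
    return math.degrees(lat2), (math.degrees(lon2) + 540.0) % 360.0 - 180.0


def position_to_range_bearing(
    origin: tuple[float, float],
    target: tuple[float, float],
    radius_m: float = EARTH_RADIUS_M,
) -> tuple[float, float]:
    """Inverse geodesic: great-circle range (m) and initial true bearing
    (deg) from ``origin`` to ``target``."""
    lat1, lon1 = map(math.radians, origin)
    lat2, lon2 = map(math.radians, target)
    dlon = lon2 - lon1
    # haversine for numerical stability at short range
    a = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    )
    dist = 2 * radius_m * math.asin(min(1.0, math.sqrt(a)))
    brg = math.atan2(
        math.sin(dlon) * math.cos(lat2),
        math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon),
    )
    return dist, math.degrees(brg) % 360.0


def camera_transit_time(
    offshore_distribution,
    speed_mps: float = 1.6,
    hfov_deg: float = 6.2,
) -> TransitTime:
    """Mean time (minutes) a whale takes to cross the camera field of view.

    At offshore range r the camera wedge subtends an arc of length
    ``2*pi*(hfov/360)*r``; dividing by swim speed and averaging over the
    sighting-derived offshore distribution gives

        t_SA = 2*pi*(hfov/360) * sum_j w_j * r_j / s

    with w_j the normalized whale-count weights at range r_j.
    """
    if speed_mps <= 0:
        raise ValueError("swim speed must be positive")
    ranges = np.asarray(offshore_distribution.ranges_m, dtype=float)
    weights = np.asarray(offshore_distribution.weights, dtype=float)
    if ranges.size == 0 or weights.sum() <= 0:
        raise ValueError("offshore distribution is empty")
    w = weights / weights.sum()
    seconds = 2.0 * math.pi * (hfov_deg / 360.0) * float(np.sum(w * ranges)) / speed_mps
    return TransitTime(value_minutes=seconds / 60.0, search_area_label="camera")


def acoustic_transit_time(
    geom: SurveyGeometry | None = None,
    speed_mps: float = 1.6,
    distance_m: float | None = None,
) -> TransitTime:
    """Mean time (minutes) a whale takes to cross the hydrophone array,
    i.e. the along-migration array extent divided by swim speed."""
    if speed_mps <= 0:
        raise ValueError("swim speed must be positive")
    if distance_m is None:
        distance_m = (geom or SurveyGeometry()).array_transit_distance_m
    if distance_m < 0:
        raise ValueError("transit distance must be nonnegative")
    return TransitTime(value_minutes=distance_m / speed_mps / 60.0, search_area_label="acoustic")
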