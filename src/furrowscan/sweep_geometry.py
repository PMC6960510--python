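"""Angular bookkeeping and polar→Cartesian conversion for 2D lidar sweeps.

A sweep is an ordered set of distance returns from a rotating 2D scanning
laser mounted nadir-down on a moving boom.  The device reports one distance
per *optical angle*; angles are spaced at a fixed angular resolution
(0.36° for the sensors modeled here) and are indexed from the first reported
angle.  All public angles are in degrees measured from nadir (straight
down); positive angles point toward increasing easting.

The indexing convention is: index 0 is the starting optical angle
(``+start_offset`` degrees from nadir) and each subsequent index decreases
the angle by one resolution step, so for the default 90° field of view the
nadir beam lands exactly at index 125 (45 / 0.36).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

# Guard against binary floating point representation of decimal degree
# steps (e.g. 270/0.36 evaluates to 749.9999... in double precision).
_EPS = 1e-9


def optical_angle_count(fov: float, resolution: float) -> int:
    """Number of optical angles spanning ``fov`` at ``resolution`` spacing.

    Both endpoints are counted, so a 270° sweep at 0.36° yields 751 angles
    and the reduced 90° sweep yields 251.

    Parameters
    ----------
    fov : float
        Angular span in degrees; must be >= 0.
    resolution : float
        Spacing between adjacent optical angles in degrees; must be > 0.
    """
    if resolution <= 0:
        raise ParameterError(f"angular resolution must be positive, got {resolution}")
    if fov < 0:
        raise ParameterError(f"fov must be non-negative, got {fov}")
    return int(math.floor(fov / resolution * (1 + 1e-12) + _EPS)) + 1


@dataclass(frozen=True)
class SensorGeometry:
    """Angular layout, mount height and output rate of one lidar unit.

    Attributes
    ----------
    angular_resolution : float
        Degrees between adjacent optical angles (device-fixed, 0.36).
    fov : float
        Effective field of view in degrees (device maximum 270, operated
        at 90 for data reduction).
    start_offset : float
        Degrees from nadir of index 0.  Defaults to ``fov / 2`` so the
        sweep is symmetric about nadir.
    mount_height_mm : float
        Nominal sensor-origin height above the reference surface, mm.
    scan_rate_hz : float
        Internal mirror rotation rate (device-fixed, 32 Hz).
    output_rate_hz : float
        Message output rate of the controller (5 Hz operating point).
    """

    angular_resolution: float = 0.36
    fov: float = 90.0
    start_offset: float = field(default=None)  # type: ignore[assignment]
    mount_height_mm: float = 1682.0
    scan_rate_hz: float = 32.0
    output_rate_hz: float = 5.0

    def __post_init__(self):
        if self.angular_resolution <= 0:
            raise ParameterError("angular_resolution must be positive")
        if self.fov < 0:
            raise ParameterError("fov must be non-negative")
        if self.start_offset is None:
            object.__setattr__(self, "start_offset", self.fov / 2.0)

    @property
    def n_angles(self) -> int:
        return optical_angle_count(self.fov, self.angular_resolution)

    @property
    def nadir_index(self) -> int:
        """Index of the straight-down beam (center of an odd-count sweep)."""
        return (self.n_angles - 1) // 2

    def angles(self) -> np.ndarray:
        """Degrees-from-nadir for every index, shape ``(n_angles,)``."""
        return self.start_offset - np.arange(self.n_angles) * self.angular_resolution


def angle_of_index(i: int, geom: SensorGeometry) -> float:
    """Degrees from nadir of optical-angle index ``i``.

    Index 0 is at ``+start_offset``; the angle decreases by one resolution
    step per index (index 125 is nadir for the default geometry).
    """
    if not 0 <= i < geom.n_angles:
        raise IndexError(f"optical-angle index {i} outside [0, {geom.n_angles})")
    return geom.start_offset - i * geom.angular_resolution


@dataclass(frozen=True)
class PointXZ:
    """A sweep return in the sensor's vertical plane.

    ``x`` is lateral offset from the nadir axis in mm (positive toward
    increasing easting); ``z`` is vertical drop from the sensor origin in mm
    (non-negative for any return below the sensor).
    """

    x: float
    z: float


def polar_to_xz(distance: float, angle: float) -> PointXZ:
    """Convert a (distance, degrees-from-nadir) return to Cartesian (x, z).

    ``x = d·sin(angle)``, ``z = d·cos(angle)``; for ``|angle| < 90`` the
    vertical drop z is positive and ``x² + z² = d²``.
    """
    if distance < 0:
        raise ParameterError(f"distance must be non-negative, got {distance}")
    if abs(angle) > 135:
        raise ParameterError(f"|angle| must be <= 135 degrees, got {angle}")
    a = math.radians(angle)
    return PointXZ(x=distance * math.sin(a), z=distance * math.cos(a))


def xz_to_polar(x: float, z: float) -> tuple[float, float]:
    """Inverse of :func:`polar_to_xz` for returns below the sensor (z > 0)."""
    return math.hypot(x, z), math.degrees(math.atan2(x, z))


def center_window_indices(window: float, geom: SensorGeometry) -> np.ndarray:
    """Indices of the smallest symmetric run about nadir spanning ``window``°.

    Returns an odd-length index array centered on the nadir index whose
    angular span ``(count − 1)·resolution`` is the smallest one >= ``window``.
    The initialization algorithm uses the 10° window, i.e. 29 values for the
    default geometry.
    """
    if not 0 <= window <= geom.fov:
        raise ParameterError(f"window must lie in [0, fov={geom.fov}], got {window}")
    if geom.n_angles % 2 != 1:
        raise ParameterError("center window requires an odd optical-angle count")
    half = int(math.ceil(window / (2 * geom.angular_resolution) - _EPS))
    nadir = geom.nadir_index
    if half > nadir:
        raise ParameterError("window exceeds symmetric range about nadir")
    return np.arange(nadir - half, nadir + half + 1)
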