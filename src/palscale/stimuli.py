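"""Parametric model of progressive-addition-lens (PAL) distortion fields.

A PAL combines a far correction (spherical power ``Sph``, signed diopters)
with a near addition (``Add``, non-negative diopters).  The geometric
distortion such a lens imposes on the visual field follows a pincushion
pattern for positive ``Sph`` and a barrel pattern for negative ``Sph``, with
an additional asymmetry between the upper (far) and lower (near) field that
grows with ``Add``.

This module provides a two-term parametric stand-in for ray-traced lens
distortions: a cubic radial term carrying the pincushion/barrel shape and an
``Add``-weighted lower-field term carrying the near-zone asymmetry.  The
fields give synthetic ground-truth perceptual scales a physical anchor; the
constants are configuration for the simulator, not claims about any real
lens design.

Coordinates are head-relative longitude/latitude in degrees of visual angle,
origin at straight-ahead, latitude positive upward.  Fields live on a regular
lattice (default 1 degree spacing) and displacements are in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "LensSpec",
    "REFERENCE_LENS",
    "DEFAULT_CATCH_LENS",
    "FrameAperture",
    "GridSpec",
    "DistortionField",
    "make_distortion_field",
    "severity_index",
    "warp_points",
    "field_to_frame",
    "field_from_frame",
    "K_RADIAL",
    "K_LOWER_FIELD",
]

# Radial (pincushion/barrel) gain: deg of displacement per deg^3 of
# eccentricity per dpt of |Sph|.  Chosen so the peak displacement at the
# aperture edge for a strong lens (sph=5, add=3) is a few degrees.
K_RADIAL = 4e-6
# Lower-field (near-zone) gain: deg of displacement per deg eccentricity per
# deg below the horizon per dpt of Add.  Subordinate to the radial term so
# the exaggerated catch lens always dominates the severity ordering.
K_LOWER_FIELD = 2e-5


@dataclass(frozen=True, order=True)
class LensSpec:
    """One stimulus condition: a lens of far power ``sph`` and addition ``add``.

    The undistorted reference condition is the unique lens with
    ``sph == 0``, ``add == 0`` and ``is_reference=True``.
    """

    sph: float
    add: float = 0.0
    is_reference: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sph) and np.isfinite(self.add)):
            raise ValueError("lens powers must be finite")
        if self.add < 0:
            raise ValueError(f"add power must be non-negative, got {self.add}")
        if self.is_reference and (self.sph != 0 or self.add != 0):
            raise ValueError("the reference condition must have sph=0 and add=0")

    def __str__(self) -> str:
        if self.is_reference:
            return "undistorted"
        return f"sph={self.sph:+g}/add={self.add:g}"


#: The undistorted reference condition.
REFERENCE_LENS = LensSpec(0.0, 0.0, is_reference=True)

#: Exaggerated lens used in catch (trivial) trials.  add=1 keeps it on the
#: synthetic observers' ground-truth scale.
DEFAULT_CATCH_LENS = LensSpec(8.0, 1.0)


@dataclass(frozen=True)
class FrameAperture:
    """Elliptic spectacle-frame aperture, in degrees of visual angle.

    Defaults model a 116 x 80 degree inner frame ellipse (half-width 58,
    half-height 40) with a 2 degree rim.
    """

    half_width: float = 58.0
    half_height: float = 40.0
    rim_thickness: float = 2.0

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.half_height <= 0:
            raise ValueError("aperture half-axes must be positive")

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the inner ellipse."""
        return (lon / self.half_width) ** 2 + (lat / self.half_height) ** 2 <= 1.0


@dataclass(frozen=True)
class GridSpec:
    """Rectangular lon/lat lattice: extent (degrees) and spacing (degrees)."""

    lon_min: float = -60.0
    lon_max: float = 60.0
    lat_min: float = -45.0
    lat_max: float = 45.0
    spacing: float = 1.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("grid extent is empty")

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        lon = np.arange(self.lon_min, self.lon_max + 0.5 * self.spacing, self.spacing)
        lat = np.arange(self.lat_min, self.lat_max + 0.5 * self.spacing, self.spacing)
        return lon, lat


@dataclass(frozen=True)
class DistortionField:
    """Displacement field of one lens over a regular lon/lat lattice.

    ``dx``/``dy`` hold the longitudinal/latitudinal displacement in degrees,
    shaped ``(len(lat), len(lon))``.
    """

    lon: np.ndarray
    lat: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    lens: LensSpec = field(default=REFERENCE_LENS)

    def __post_init__(self) -> None:
        expected = (self.lat.size, self.lon.size)
        if self.dx.shape != expected or self.dy.shape != expected:
            raise ValueError("displacement arrays must be shaped (n_lat, n_lon)")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("displacements must be finite")

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.dx, self.dy)


def make_distortion_field(lens: LensSpec, grid: GridSpec | None = None) -> DistortionField:
    """Evaluate the parametric displacement field of ``lens`` on a lattice.

    The displacement at field position ``(lon, lat)`` with eccentricity
    ``r`` is radial:

    ``d = [sign(sph) * k1 * |sph| * r^3 + k2 * add * max(0, -lat) * r] * r_hat``

    The first term is a pure pincushion (sph > 0, outward) or barrel
    (sph < 0, inward) distortion; the second adds near-zone (lower-field)
    distortion growing with ``add``.  The reference lens yields an exactly
    zero field.
    """
    grid = grid or GridSpec()
    lon, lat = grid.axes()
    lon2d, lat2d = np.meshgrid(lon, lat)
    r = np.hypot(lon2d, lat2d)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, lon2d / r, 0.0)
        uy = np.where(r > 0, lat2d / r, 0.0)
    radial = np.sign(lens.sph) * K_RADIAL * abs(lens.sph) * r**3
    lower = K_LOWER_FIELD * lens.add * np.maximum(0.0, -lat2d) * r
    mag = radial + lower
    return DistortionField(lon=lon, lat=lat, dx=mag * ux, dy=mag * uy, lens=lens)


def severity_index(field_: DistortionField, aperture: FrameAperture | None = None) -> float:
    """RMS displacement magnitude (degrees) over lattice nodes inside the aperture.

    A scalar physical summary of how distorted a lens is; zero iff the field
    vanishes inside the aperture.  Invariant under horizontal mirroring of
    the field (the two eyes see mirrored copies of the same distortion).
    """
    aperture = aperture or FrameAperture()
    lon2d, lat2d = np.meshgrid(field_.lon, field_.lat)
    inside = aperture.contains(lon2d, lat2d)
    if not inside.any():
        raise ValueError("aperture does not intersect the field grid")
    mag2 = field_.dx[inside] ** 2 + field_.dy[inside] ** 2
    return float(np.sqrt(mag2.mean()))


def warp_points(field_: DistortionField, points: np.ndarray) -> np.ndarray:
    """Displace visual-field points by the bilinearly interpolated field.

    Parameters
    ----------
    points : array of shape (n, 2)
        ``(lon, lat)`` coordinates in degrees; must lie within the grid extent.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) arrays of (lon, lat)")
    lon, lat = field_.lon, field_.lat
    out_of_range = (
        (pts[:, 0] < lon[0]) | (pts[:, 0] > lon[-1])
        | (pts[:, 1] < lat[0]) | (pts[:, 1] > lat[-1])
    )
    if out_of_range.any():
        bad = pts[out_of_range][0]
        raise ValueError(f"point ({bad[0]:g}, {bad[1]:g}) lies outside the field grid")
    # interpolators index (lat, lon) to match the storage layout
    interp_x = RegularGridInterpolator((lat, lon), field_.dx, method="linear")
    interp_y = RegularGridInterpolator((lat, lon), field_.dy, method="linear")
    query = pts[:, ::-1]
    disp = np.column_stack([interp_x(query), interp_y(query)])
    return pts + disp


def field_to_frame(field_: DistortionField) -> pd.DataFrame:
    """Serialize a field to long format with columns lon, lat, dx, dy."""
    lon2d, lat2d = np.meshgrid(field_.lon, field_.lat)
    return pd.DataFrame(
        {
            "lon": lon2d.ravel(),
            "lat": lat2d.ravel(),
            "dx": field_.dx.ravel(),
            "dy": field_.dy.ravel(),
        }
    )


def field_from_frame(frame: pd.DataFrame, lens: LensSpec = REFERENCE_LENS) -> DistortionField:
    """Rebuild a :class:`DistortionField` from its long-format serialization."""
    lon = np.unique(frame["lon"].to_numpy())
    lat = np.unique(frame["lat"].to_numpy())
    shape = (lat.size, lon.size)
    if len(frame) != lon.size * lat.size:
        raise ValueError("frame does not cover a full regular lattice")
    order = np.lexsort((frame["lon"].to_numpy(), frame["lat"].to_numpy()))
    dx = frame["dx"].to_numpy()[order].reshape(shape)
    dy = frame["dy"].to_numpy()[order].reshape(shape)
    return DistortionField(lon=lon, lat=lat, dx=dx, dy=dy, lens=lens)
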