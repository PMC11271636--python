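"""Spherical geometry primitives: geographic points, great-circle distance, centroids.

All public interfaces take and return coordinates in decimal degrees; radians
are used only internally. Distances are kilometres on a sphere of radius
6371 km (geodesics on an ellipsoid are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: Upper bound of any great-circle distance (half the circumference).
MAX_DISTANCE_KM = np.pi * EARTH_RADIUS_KM


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere, in decimal degrees.

    Latitude must lie in [-90, 90]; longitude in (-180, 180].
    """

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lat) or not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat!r} outside [-90, 90]")
        if not np.isfinite(self.lon) or not (-180.0 < self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon!r} outside (-180, 180]")


def haversine(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance between two points, in km.

    Canonical haversine: ``2 R arcsin sqrt(sin^2(dlat/2) +
    cos(lat_a) cos(lat_b) sin^2(dlon/2))``. Symmetric, non-negative and
    bounded by pi * R.
    """
    phi1, phi2 = np.radians(a.lat), np.radians(b.lat)
    dphi = phi2 - phi1
    dlam = np.radians(b.lon) - np.radians(a.lon)
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # Clip guards tiny negative / >1 round-off before the arcsin.
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def haversine_matrix(lats: np.ndarray, lons: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distance matrix (km) for coordinate arrays in degrees."""
    phi = np.radians(np.asarray(lats, dtype=float))[:, None]
    lam = np.radians(np.asarray(lons, dtype=float))[:, None]
    dphi = phi - phi.T
    dlam = lam - lam.T
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi) * np.cos(phi.T) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def spherical_centroid(points: list[GeoPoint]) -> GeoPoint:
    """Centroid of points computed on the unit sphere, returned in degrees.

    Coordinates are averaged as 3-D unit vectors and the mean is projected
    back, which avoids longitude wrap-around artefacts of naive averaging.
    """
    if not points:
        raise ValueError("cannot take the centroid of zero points")
    phi = np.radians([p.lat for p in points])
    lam = np.radians([p.lon for p in points])
    x = np.cos(phi) * np.cos(lam)
    y = np.cos(phi) * np.sin(lam)
    z = np.sin(phi)
    mx, my, mz = x.mean(), y.mean(), z.mean()
    norm = np.sqrt(mx * mx + my * my + mz * mz)
    if norm < 1e-12:
        # Antipodal degenerate configuration; fall back to the equator/prime meridian.
        return GeoPoint(0.0, 0.0)
    lat = float(np.degrees(np.arcsin(mz / norm)))
    lon = float(np.degrees(np.arctan2(my, mx)))
    if lon <= -180.0:
        lon += 360.0
    return GeoPoint(lat, lon)
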