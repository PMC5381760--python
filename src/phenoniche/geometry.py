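"""Geodesic helpers: haversine distances and a local planar km projection.

All record coordinates are WGS84 decimal degrees.  For point-pattern work the
records are projected with a local equirectangular transform about the mean
latitude; adequate at the sub-continental extents used here.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between coordinate pairs (degrees)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(lon, lat) -> np.ndarray:
    """Full pairwise distance matrix in km (brute force, O(n^2))."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


class LocalProjection:
    """Equirectangular lon/lat <-> km plane about a reference point."""

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._kx = EARTH_RADIUS_KM * np.cos(np.radians(lat0)) * np.pi / 180.0
        self._ky = EARTH_RADIUS_KM * np.pi / 180.0

    @classmethod
    def for_points(cls, lon, lat) -> "LocalProjection":
        return cls(float(np.mean(lon)), float(np.mean(lat)))

    def forward(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon - self.lon0) * self._kx, (lat - self.lat0) * self._ky

    def inverse(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return x / self._kx + self.lon0, y / self._ky + self.lat0
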