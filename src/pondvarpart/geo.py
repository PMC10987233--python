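"""Planar projection helpers.

Study extents are ~100 km, so an equirectangular projection about the site
centroid is accurate to well under 1% — no geodetic machinery needed.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def to_planar_km(
    longitude: np.ndarray,
    latitude: np.ndarray,
    *,
    lon0: float | None = None,
    lat0: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to planar x/y in km about the centroid.

    Equirectangular: x = R·cos(lat0)·Δλ, y = R·Δφ (radians).
    """
    longitude = np.asarray(longitude, dtype=float)
    latitude = np.asarray(latitude, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(longitude))
    if lat0 is None:
        lat0 = float(np.mean(latitude))
    x = EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0)) * np.deg2rad(longitude - lon0)
    y = EARTH_RADIUS_KM * np.deg2rad(latitude - lat0)
    return x, y


def from_planar_km(
    x_km: np.ndarray,
    y_km: np.ndarray,
    *,
    lon0: float = -0.5,
    lat0: float = 39.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`to_planar_km` about a reference point.

    Used by the simulator, which works in planar km internally but emits
    longitude/latitude so that synthetic files look like field files.
    """
    x_km = np.asarray(x_km, dtype=float)
    y_km = np.asarray(y_km, dtype=float)
    lon = lon0 + np.rad2deg(x_km / (EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))))
    lat = lat0 + np.rad2deg(y_km / EARTH_RADIUS_KM)
    return lon, lat
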