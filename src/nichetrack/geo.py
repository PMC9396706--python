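"""Spherical geometry helpers: great-circle distances and the azimuthal
equidistant projection used to planarise tracks.

All distances are in kilometres on a sphere of radius 6371 km.  The azimuthal
equidistant projection centred at a track's origin preserves distance and
azimuth from that origin exactly, which makes net squared displacement computed
in the projected plane equal to squared great-circle distance from the origin.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def _check_lonlat(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    return lon, lat


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points, elementwise, in km."""
    lon1, lat1 = _check_lonlat(lon1, lat1)
    lon2, lat2 = _check_lonlat(lon2, lat2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def aeqd_forward(lon, lat, lon0: float, lat0: float):
    """Project lon/lat (degrees) to planar (x, y) km, azimuthal equidistant
    about (lon0, lat0).  x is locally east, y locally north."""
    lon, lat = _check_lonlat(lon, lat)
    _check_lonlat(lon0, lat0)
    phi = np.radians(lat)
    phi0 = np.radians(lat0)
    dlam = np.radians(lon) - np.radians(lon0)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(dlam)
    c = np.arccos(np.clip(cos_c, -1.0, 1.0))
    sin_c = np.sin(c)
    # k = c / sin(c) -> 1 as c -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(sin_c > 1e-15, c / np.where(sin_c > 1e-15, sin_c, 1.0), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(dlam)
    )
    return x, y


def aeqd_inverse(x, y, lon0: float, lat0: float):
    """Inverse of :func:`aeqd_forward`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_lonlat(lon0, lat0)
    phi0 = np.radians(lat0)
    lam0 = np.radians(lon0)
    rho = np.hypot(x, y)
    c = rho / EARTH_RADIUS_KM
    sin_c, cos_c = np.sin(c), np.cos(c)
    safe_rho = np.where(rho > 1e-15, rho, 1.0)
    phi = np.arcsin(
        np.clip(cos_c * np.sin(phi0) + (y / safe_rho) * sin_c * np.cos(phi0), -1.0, 1.0)
    )
    lam = lam0 + np.arctan2(
        x * sin_c, safe_rho * cos_c * np.cos(phi0) - y * sin_c * np.sin(phi0)
    )
    phi = np.where(rho > 1e-15, phi, phi0)
    lam = np.where(rho > 1e-15, lam, lam0)
    lon = np.degrees(lam)
    # keep longitudes in [-180, 180]
    lon = (lon + 180.0) % 360.0 - 180.0
    return lon, np.degrees(phi)
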