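"""Azimuthal equidistant projection between lon/lat and a local planar frame.

Movement modeling and track simulation are done on a plane in kilometers;
positions are converted to and from geographic coordinates with a spherical
azimuthal equidistant projection centered on the study area.  Distances from
the center are exact; distortion elsewhere is negligible at the few-hundred-km
scale of an island-associated deployment.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def geo_to_plane(lon, lat, center_lon: float, center_lat: float):
    """Project lon/lat (degrees) to planar x/y kilometers (east, north)."""
    lon, lat = np.asarray(lon, float), np.asarray(lat, float)
    lam, phi = np.deg2rad(lon), np.deg2rad(lat)
    lam0, phi0 = np.deg2rad(center_lon), np.deg2rad(center_lat)
    cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    k = np.where(c > 1e-12, c / np.where(c > 1e-12, np.sin(c), 1.0), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
    y = EARTH_RADIUS_KM * k * (
        np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
    )
    return x, y


def plane_to_geo(x, y, center_lon: float, center_lat: float):
    """Inverse projection: planar kilometers back to lon/lat degrees."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    lam0, phi0 = np.deg2rad(center_lon), np.deg2rad(center_lat)
    r = np.hypot(x, y)
    c = r / EARTH_RADIUS_KM
    with np.errstate(invalid="ignore", divide="ignore"):
        sin_c, cos_c = np.sin(c), np.cos(c)
        phi = np.arcsin(
            np.where(r > 1e-12,
                     cos_c * np.sin(phi0) + y * sin_c * np.cos(phi0) / np.where(r > 1e-12, r, 1.0),
                     np.sin(phi0))
        )
        lam = lam0 + np.arctan2(
            x * sin_c,
            r * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c,
        )
        lam = np.where(r > 1e-12, lam, lam0)
    return np.rad2deg(lam), np.rad2deg(phi)
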