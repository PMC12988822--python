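"""Spherical azimuthal-equidistant projection (km units).

Ingest convenience for lon/lat track data; the analysis itself is planar.
Centred by default on the data centroid.  Accuracy is the spherical-earth
approximation, ample for regional telemetry work.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

__all__ = ["aeqd_forward", "aeqd_inverse", "project_tracks"]


def aeqd_forward(lon, lat, lon0: float, lat0: float):
    lon, lat = np.radians(lon), np.radians(lat)
    lon0, lat0 = np.radians(lon0), np.radians(lat0)
    cos_c = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(lon - lon0)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)
    k = np.where(c > 1e-12, c / np.maximum(np.sin(c), 1e-300), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(lon - lon0)
    y = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat)
                               - np.sin(lat0) * np.cos(lat) * np.cos(lon - lon0))
    return x, y


def aeqd_inverse(x, y, lon0: float, lat0: float):
    x = np.asarray(x, float) / EARTH_RADIUS_KM
    y = np.asarray(y, float) / EARTH_RADIUS_KM
    lat0, lon0r = np.radians(lat0), np.radians(lon0)
    c = np.hypot(x, y)
    with np.errstate(invalid="ignore", divide="ignore"):
        lat = np.where(c > 1e-12,
                       np.arcsin(np.cos(c) * np.sin(lat0)
                                 + y * np.sin(c) * np.cos(lat0) / np.maximum(c, 1e-300)),
                       lat0)
        lon = lon0r + np.arctan2(
            x * np.sin(c),
            c * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c))
        lon = np.where(c > 1e-12, lon, lon0r)
    return np.degrees(lon), np.degrees(lat)


def project_tracks(df, lon_col: str = "lon", lat_col: str = "lat",
                   center=None):
    """Add planar ``x``/``y`` (km) columns; returns (frame, (lon0, lat0))."""
    lon0, lat0 = center if center is not None else (
        float(df[lon_col].mean()), float(df[lat_col].mean()))
    out = df.copy()
    out["x"], out["y"] = aeqd_forward(df[lon_col].to_numpy(float),
                                      df[lat_col].to_numpy(float), lon0, lat0)
    return out, (lon0, lat0)
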