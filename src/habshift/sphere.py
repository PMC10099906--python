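"""Spherical geometry primitives shared across the pipeline.

All functions assume a spherical Earth of radius ``EARTH_RADIUS_KM`` and
operate on longitude/latitude in decimal degrees.  They are vectorised:
scalar or array inputs broadcast in the usual numpy fashion.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "great_circle_distance",
    "initial_bearing",
    "destination",
    "slerp",
    "signed_turn",
    "wrap_lon",
]


def wrap_lon(lon):
    """Normalise longitude(s) to [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def great_circle_distance(lon1, lat1, lon2, lat2):
    """Haversine great-circle distance in km on a sphere of radius 6371 km."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards against rounding slightly above 1 for antipodal points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def destination(lon, lat, bearing_deg, distance_km):
    """Forward geodesic on the sphere: point reached from (lon, lat) moving
    ``distance_km`` along the great circle with the given initial bearing."""
    lon, lat, brg = (np.radians(np.asarray(x, dtype=float))
                     for x in (lon, lat, bearing_deg))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat) * np.cos(delta)
                     + np.cos(lat) * np.sin(delta) * np.cos(brg))
    lon2 = lon + np.arctan2(np.sin(brg) * np.sin(delta) * np.cos(lat),
                            np.cos(delta) - np.sin(lat) * np.sin(lat2))
    return wrap_lon(np.degrees(lon2)), np.degrees(lat2)


def _to_unit_xyz(lon, lat):
    lon, lat = np.radians(lon), np.radians(lat)
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def _from_unit_xyz(v):
    x, y, z = v[..., 0], v[..., 1], v[..., 2]
    return wrap_lon(np.degrees(np.arctan2(y, x))), np.degrees(np.arcsin(np.clip(z, -1, 1)))


def slerp(lon1, lat1, lon2, lat2, frac):
    """Spherical linear interpolation between two points.

    ``frac`` in [0, 1]; 0 returns point 1, 1 returns point 2.  Handles the
    antimeridian naturally by interpolating on the unit sphere.
    """
    p1 = _to_unit_xyz(np.asarray(lon1, float), np.asarray(lat1, float))
    p2 = _to_unit_xyz(np.asarray(lon2, float), np.asarray(lat2, float))
    frac = np.asarray(frac, dtype=float)[..., None]
    omega = np.arccos(np.clip((p1 * p2).sum(axis=-1, keepdims=True), -1.0, 1.0))
    small = omega < 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        w1 = np.where(small, 1.0 - frac, np.sin((1.0 - frac) * omega) / np.sin(omega))
        w2 = np.where(small, frac, np.sin(frac * omega) / np.sin(omega))
    v = w1 * p1 + w2 * p2
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    return _from_unit_xyz(v)


def signed_turn(bearing_prev, bearing_next):
    """Signed turning angle (degrees in (-180, 180]) between successive
    bearings; positive = clockwise."""
    d = (np.asarray(bearing_next, float) - np.asarray(bearing_prev, float)) % 360.0
    d = np.where(d > 180.0, d - 360.0, d)
    # map -180 exactly to +180 so the convention (-180, 180] holds
    return np.where(d == -180.0, 180.0, d)
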