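"""Great-circle geometry helpers on the WGS84 sphere.

All public functions take decimal-degree longitude/latitude and return
kilometres or degrees. A spherical Earth (mean radius 6371.0088 km) is
used throughout; at the study scale (<1000 km) the error versus an
ellipsoidal model is well below the positional uncertainty of the
population centroids.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

#: Eight 45-degree compass sectors, centred on the principal directions.
COMPASS_SECTORS = ("N", "NE", "E", "SE", "S", "SW", "W", "NW")


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points (broadcasts like numpy)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats):
    """Symmetric distance matrix (km) for coordinate vectors."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, degrees in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


def bearing_sector(bearing_deg):
    """Bin a bearing (degrees) into one of eight 45-degree compass sectors."""
    idx = np.mod(np.rint(np.asarray(bearing_deg, dtype=float) / 45.0).astype(int), 8)
    if idx.ndim == 0:
        return COMPASS_SECTORS[int(idx)]
    return np.array([COMPASS_SECTORS[i] for i in idx.ravel()]).reshape(idx.shape)


def aeqd_project_km(lon, lat, lon0, lat0):
    """Azimuthal equidistant projection centred at (lon0, lat0), in km.

    Distances from the centre are exact great-circle distances, which is the
    property the sliding-window grid relies on.
    """
    d = haversine_km(lon0, lat0, lon, lat)
    theta = np.radians(initial_bearing_deg(lon0, lat0, lon, lat))
    return d * np.sin(theta), d * np.cos(theta)


def aeqd_unproject(x_km, y_km, lon0, lat0):
    """Inverse of :func:`aeqd_project_km` (spherical direct geodesic problem)."""
    x_km = np.asarray(x_km, dtype=float)
    y_km = np.asarray(y_km, dtype=float)
    d = np.hypot(x_km, y_km) / EARTH_RADIUS_KM
    theta = np.arctan2(x_km, y_km)
    lat0r = np.radians(lat0)
    lon0r = np.radians(lon0)
    lat = np.arcsin(np.sin(lat0r) * np.cos(d) + np.cos(lat0r) * np.sin(d) * np.cos(theta))
    lon = lon0r + np.arctan2(np.sin(theta) * np.sin(d) * np.cos(lat0r),
                             np.cos(d) - np.sin(lat0r) * np.sin(lat))
    return np.degrees(lon), np.degrees(lat)
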